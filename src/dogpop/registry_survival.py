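"""Survival-adjusted registry counts.

A breed registry records new registrations but no deaths, so the living
registered subpopulation at a reference year is the sum over registration
cohorts of the cohort size times the probability of surviving to its current
age:  N = sum_y count_y * S(reference_year - y).

Uncertainty comes from the survival curve: each Monte-Carlo draw perturbs
the whole curve by a single normal deviate scaled by the per-age standard
deviation (fully correlated across ages), reflecting pooled all-breed
survival uncertainty; independent per-age noise would largely cancel in the
sum and understate the interval width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegistrationSeries",
    "SurvivalCurve",
    "SubpopulationEstimate",
    "living_registered",
    "living_registered_ci",
    "normal_summary",
]


@dataclass
class RegistrationSeries:
    years: np.ndarray
    counts: np.ndarray
    survival: "SurvivalCurve | None" = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts)
        if len(self.years) != len(self.counts):
            raise ValueError("years and counts must align")
        if (np.diff(self.years) <= 0).any():
            raise ValueError("years must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "count": self.counts})


@dataclass
class SurvivalCurve:
    """S(age) on whole years with a per-age variance."""

    ages: np.ndarray
    survival: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.variance is None:
            self.variance = np.zeros_like(self.survival)
        self.variance = np.asarray(self.variance, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (len(self.ages) == len(self.survival) == len(self.variance)):
            raise ValueError("ages, survival, variance must align")
        if (np.diff(self.ages) <= 0).any():
            raise ValueError("ages must be strictly increasing")
        if ((self.survival < 0) | (self.survival > 1)).any():
            raise ValueError("survival probabilities must be in [0, 1]")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be non-increasing in age")
        if (self.variance < 0).any():
            raise ValueError("variances must be nonnegative")

    def s(self, age: int) -> float:
        """S(age); ages beyond the curve are treated as 0 (nobody survives)."""
        if age > int(self.ages.max()):
            return 0.0
        hits = np.flatnonzero(self.ages == age)
        if not hits.size:
            raise ValueError(
                f"survival undefined at age {age} and no extrapolation rule applies"
            )
        return float(self.survival[hits[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_years": self.ages, "survival": self.survival, "variance": self.variance}
        )


@dataclass
class SubpopulationEstimate:
    source: str
    median: float
    ci_low: float
    ci_high: float
    draws: np.ndarray | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("need ci_low <= median <= ci_high")

    @classmethod
    def from_draws(cls, source: str, draws) -> "SubpopulationEstimate":
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return cls(
            source,
            float(np.median(draws)),
            float(lo),
            float(hi),
            draws,
            float(draws.mean()),
            float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        )


def living_registered(
    series: RegistrationSeries, survival: SurvivalCurve, reference_year: int
) -> float:
    """Point estimate of the living registered subpopulation."""
    if reference_year < int(series.years.max()):
        raise ValueError("reference_year must not precede the last series year")
    return float(
        sum(
            count * survival.s(reference_year - int(year))
            for year, count in zip(series.years, series.counts)
        )
    )


def living_registered_ci(
    series: RegistrationSeries,
    survival: SurvivalCurve,
    reference_year: int,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> SubpopulationEstimate:
    """Monte-Carlo interval via correlated curve-level perturbation.

    Per draw: S'(age) = clip(S(age) + z * sqrt(var(age)), 0, 1) with a single
    z ~ N(0,1) shared across ages, re-monotonised by a cumulative minimum,
    then the cohort sum is recomputed.
    """
    ages = reference_year - series.years.astype(int)
    if (ages > survival.ages.max()).all() and not len(series.years):
        raise ValueError("empty series")
    s = np.asarray([survival.s(int(a)) if a <= survival.ages.max() else 0.0 for a in ages])
    # per-needed-age sd, 0 beyond the curve
    sd = np.asarray(
        [
            float(np.sqrt(survival.variance[np.flatnonzero(survival.ages == a)[0]]))
            if a <= survival.ages.max() and (survival.ages == a).any()
            else 0.0
            for a in ages
        ]
    )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_draws)
    curves = np.clip(s[None, :] + z[:, None] * sd[None, :], 0.0, 1.0)
    # enforce monotone non-increasing survival along increasing age
    order = np.argsort(ages)  # ascending age
    curves_sorted = curves[:, order]
    curves_sorted = np.minimum.accumulate(curves_sorted, axis=1)
    curves[:, order] = curves_sorted
    totals = curves @ series.counts.astype(float)
    est = SubpopulationEstimate.from_draws("kc", totals)
    return est


def normal_summary(subpop: SubpopulationEstimate) -> tuple[float, float]:
    """(mean, sd) summary for feeding a Normal subpopulation model.

    With draws available, uses their median and sample SD; given only a 95%
    interval, sd = (ci_high - ci_low) / 3.92.
    """
    if subpop.draws is not None and subpop.draws.size:
        d = subpop.draws
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        return float(np.median(d)), sd
    return subpop.median, (subpop.ci_high - subpop.ci_low) / 3.92
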