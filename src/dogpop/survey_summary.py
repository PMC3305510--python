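"""Quota filtering and descriptive summaries of the ownership survey.

Covers the per-area summary table (ownership percentages, mean dogs per
owning household with its standard error), raw subpopulation membership
proportions with cluster-bootstrap confidence intervals, and the three-way
membership overlap table.

The bootstrap resamples whole telephone-directory areas (clusters) with
replacement: areas are the survey's primary sampling units and ownership and
membership are strongly clustered by area, so household- or dog-level
resampling would understate the interval width.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import FLAG_NAMES, SurveyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AreaSummary",
    "MembershipSummary",
    "OverlapTable",
    "apply_quota",
    "summarize",
    "summary_frame",
    "membership_proportions",
    "venn_overlap",
]


@dataclass
class AreaSummary:
    area_id: str
    n_valid: int
    response_rate: float | None  # percent, None when call volume unknown
    n_dog_households: int
    n_dogs: int
    pct_households_with_dog: float | None
    mean_dogs_per_owning_household: float | None
    se_mean: float | None


@dataclass
class MembershipSummary:
    subpopulation: str
    count: int
    n_dogs: int
    proportion: float
    ci_low: float
    ci_high: float


@dataclass
class OverlapTable:
    """Counts of the eight (vet, insured, kc) membership combinations."""

    cells: dict[tuple[int, int, int], int]
    n_dogs: int

    def percentage(self, cell: tuple[int, int, int]) -> float:
        return 100.0 * self.cells[cell] / self.n_dogs

    def marginal(self, flag: str) -> int:
        axis = ("vet", "insured", "kc").index(flag)
        return sum(c for cell, c in self.cells.items() if cell[axis])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vet": v,
                "insured": i,
                "kc": k,
                "count": self.cells[(v, i, k)],
                "pct": self.percentage((v, i, k)),
            }
            for v, i, k in itertools.product((1, 0), repeat=3)
        ]
        return pd.DataFrame(rows)


def apply_quota(dataset: SurveyDataset, quota: int) -> SurveyDataset:
    """Retain the first ``quota`` valid calls per area, in call order.

    Invalid calls are dropped, as are the dogs of any dropped household.
    Idempotent: applying the same quota twice changes nothing.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    kept: list = []
    for area in dataset.areas:
        valid = sorted(
            (c for c in dataset.calls if c.area_id == area and c.valid),
            key=lambda c: c.call_order,
        )
        kept.extend(valid[:quota])
    kept_households = {c.household_id for c in kept}
    dogs = [d for d in dataset.dogs if d.household_id in kept_households]
    return SurveyDataset(
        list(dataset.areas), kept, dogs, dataset.n_total_calls, dataset.n_valid_calls
    )


def _household_dog_counts(dataset: SurveyDataset, area: str) -> np.ndarray:
    return np.asarray(
        [c.n_dogs for c in dataset.calls if c.area_id == area and c.valid and c.n_dogs]
    )


def summarize(
    dataset: SurveyDataset, raw: SurveyDataset | None = None
) -> tuple[list[AreaSummary], AreaSummary]:
    """Per-area summaries plus a pooled total row.

    ``dataset`` should already be quota-filtered; ``raw`` (the pre-quota call
    log) supplies per-area response rates when available.  The pooled mean
    and SE are computed from the pooled household-level sample.
    """
    raw = raw or dataset
    raw_calls = pd.DataFrame(
        {
            "area": [c.area_id for c in raw.calls],
            "valid": [c.valid for c in raw.calls],
        }
    )
    summaries = []
    pooled_counts = []
    for area in dataset.areas:
        valid_calls = [c for c in dataset.calls if c.area_id == area and c.valid]
        n_valid = len(valid_calls)
        area_raw = raw_calls[raw_calls["area"] == area]
        rate = (
            100.0 * area_raw["valid"].mean() if len(area_raw) else None
        )
        counts = _household_dog_counts(dataset, area)
        pooled_counts.append(counts)
        if n_valid == 0:
            logger.warning("area %s has no valid responses", area)
            summaries.append(
                AreaSummary(area, 0, rate, 0, 0, None, None, None)
            )
            continue
        owning = len(counts)
        n_dogs = int(counts.sum())
        mean = se = None
        if owning:
            mean = n_dogs / owning
            se = (
                float(counts.std(ddof=1) / np.sqrt(owning)) if owning > 1 else 0.0
            )
        summaries.append(
            AreaSummary(
                area,
                n_valid,
                rate,
                owning,
                n_dogs,
                100.0 * owning / n_valid,
                mean,
                se,
            )
        )
    all_counts = np.concatenate([c for c in pooled_counts if c.size] or [np.empty(0)])
    total_valid = sum(s.n_valid for s in summaries)
    owning = int(all_counts.size)
    n_dogs = int(all_counts.sum())
    total_rate = (
        100.0 * raw.n_valid_calls / raw.n_total_calls
        if raw.n_total_calls
        else (100.0 * raw_calls["valid"].mean() if len(raw_calls) else None)
    )
    total = AreaSummary(
        "Total",
        total_valid,
        total_rate,
        owning,
        n_dogs,
        100.0 * owning / total_valid if total_valid else None,
        n_dogs / owning if owning else None,
        float(all_counts.std(ddof=1) / np.sqrt(owning)) if owning > 1 else None,
    )
    return summaries, total


def summary_frame(dataset: SurveyDataset, raw: SurveyDataset | None = None) -> pd.DataFrame:
    """The per-area summary plus total row as a DataFrame (CSV-ready)."""
    rows, total = summarize(dataset, raw)
    return pd.DataFrame([vars(s) for s in rows + [total]])


def _area_flag_counts(dataset: SurveyDataset) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-area dog totals and per-area flagged-dog counts."""
    by_area = dataset.dogs_by_area()
    n = np.asarray([len(by_area[a]) for a in dataset.areas])
    y = {
        name: np.asarray(
            [sum(d.flag(name) for d in by_area[a]) for a in dataset.areas]
        )
        for name in FLAG_NAMES
    }
    return n, y


def membership_proportions(
    dataset: SurveyDataset,
    n_boot: int = 10_000,
    seed: int | None = None,
    subpopulations: tuple[str, ...] = FLAG_NAMES,
) -> list[MembershipSummary]:
    """Raw membership proportions with cluster-bootstrap 95% CIs.

    The interval is the 2.5/97.5 percentile of the pooled proportion over
    ``n_boot`` resamples of whole areas with replacement, truncated to
    [0, 1]; resamples with zero dogs are redrawn into the point estimate.
    """
    if not dataset.dogs:
        raise ValueError("membership proportions need at least one dog")
    n, y = _area_flag_counts(dataset)
    rng = np.random.default_rng(seed)
    n_areas = len(dataset.areas)
    idx = rng.integers(0, n_areas, size=(n_boot, n_areas))
    boot_n = n[idx].sum(axis=1).astype(float)
    total = int(n.sum())
    out = []
    for name in subpopulations:
        count = int(y[name].sum())
        point = count / total
        boot_y = y[name][idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            props = np.where(boot_n > 0, boot_y / np.maximum(boot_n, 1), point)
        lo, hi = np.percentile(props, [2.5, 97.5])
        out.append(
            MembershipSummary(
                name,
                count,
                total,
                point,
                float(np.clip(lo, 0, 1)),
                float(np.clip(hi, 0, 1)),
            )
        )
    return out


def venn_overlap(dataset: SurveyDataset) -> OverlapTable:
    """Exact counts of the eight (vet, insured, kc) membership cells."""
    if not dataset.dogs:
        raise ValueError("overlap table needs at least one dog")
    cells = {cell: 0 for cell in itertools.product((0, 1), repeat=3)}
    for dog in dataset.dogs:
        cells[(int(dog.vet), int(dog.insured), int(dog.kc))] += 1
    return OverlapTable(cells, len(dataset.dogs))
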