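"""Synthetic inputs for the population pipeline.

The analysis consumes four kinds of data: a quota-sampled telephone survey of
dog ownership, per-practice counts of registered dogs, an annual registry
series with a survival curve, and breed/county count tables.  None of the
original raw data are deposited, so this module generates datasets with the
statistical structure the analysis assumes, plus :func:`paper_survey_fixture`,
a deterministic reconstruction of the published per-area survey table.

Survey generation model
-----------------------
Calls within an area are valid with probability ``p_valid``.  A valid
household owns at least one dog with probability ``expit(logit(p_own) + u_a)``
where ``u_a ~ N(0, area_effect_sd)`` is a per-area effect capturing the large
between-area spread of ownership observed in practice (10-67% across areas).
An owning household holds ``1 + Poisson(extra_dog_rate)`` dogs.  Each dog's
four membership flags (veterinary-registered, insured, kennel-club
registered, travel-scheme registered) are drawn from a 16-cell joint table,
either independently per dog or with a configurable probability of reusing
the household's first draw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

FLAG_NAMES = ("vet", "insured", "kc", "pets")

__all__ = [
    "FLAG_NAMES",
    "CallRecord",
    "DogRecord",
    "SurveyDataset",
    "SurveyConfig",
    "BreedCountyConfig",
    "joint_from_marginals",
    "generate_survey",
    "generate_practice_sizes",
    "generate_registry",
    "generate_breed_county_tables",
    "synthetic_survival_curve",
    "paper_survey_fixture",
    "TABLE3_AREAS",
    "FIXTURE_MEMBERSHIP_COUNTS",
]


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class CallRecord:
    area_id: str
    call_order: int
    valid: bool
    n_dogs: int

    def __post_init__(self) -> None:
        if self.call_order < 1:
            raise ValueError("call_order must be >= 1")
        if self.n_dogs < 0:
            raise ValueError("n_dogs must be >= 0")
        if not self.valid and self.n_dogs:
            raise ValueError("invalid calls carry no dogs")

    @property
    def household_id(self) -> str:
        return f"{self.area_id}:{self.call_order}"


@dataclass(frozen=True)
class DogRecord:
    household_id: str
    area_id: str
    vet: bool
    insured: bool
    kc: bool
    pets_travel: bool

    def flag(self, name: str) -> bool:
        if name == "pets":
            return self.pets_travel
        if name not in FLAG_NAMES:
            raise KeyError(f"unknown subpopulation flag {name!r}")
        return getattr(self, name)


@dataclass
class SurveyDataset:
    """Call log plus dog-level membership flags.

    ``n_total_calls`` / ``n_valid_calls`` record the pre-quota call volume so
    that response rates survive quota filtering.
    """

    areas: list[str]
    calls: list[CallRecord]
    dogs: list[DogRecord]
    n_total_calls: int | None = None
    n_valid_calls: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        households = {c.household_id for c in self.calls if c.valid and c.n_dogs > 0}
        per_household: dict[str, int] = {}
        for dog in self.dogs:
            if dog.household_id not in households:
                raise ValueError(
                    f"dog household {dog.household_id!r} is not a valid owning call"
                )
            per_household[dog.household_id] = per_household.get(dog.household_id, 0) + 1
        declared = {
            c.household_id: c.n_dogs for c in self.calls if c.valid and c.n_dogs > 0
        }
        if declared != per_household:
            raise ValueError("per-household dog counts disagree with DogRecords")

    # -- convenience views -------------------------------------------------
    def valid_calls(self) -> list[CallRecord]:
        return [c for c in self.calls if c.valid]

    def dogs_by_area(self) -> dict[str, list[DogRecord]]:
        out: dict[str, list[DogRecord]] = {a: [] for a in self.areas}
        for dog in self.dogs:
            out[dog.area_id].append(dog)
        return out

    def flag_counts(self) -> dict[str, int]:
        return {
            name: sum(d.flag(name) for d in self.dogs) for name in FLAG_NAMES
        }

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": [c.area_id for c in self.calls],
                "call_order": [c.call_order for c in self.calls],
                "valid": [int(c.valid) for c in self.calls],
                "n_dogs": [c.n_dogs for c in self.calls],
            }
        )

    def dogs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "household_id": [d.household_id for d in self.dogs],
                "area_id": [d.area_id for d in self.dogs],
                "vet": [int(d.vet) for d in self.dogs],
                "insured": [int(d.insured) for d in self.dogs],
                "kc": [int(d.kc) for d in self.dogs],
                "pets": [int(d.pets_travel) for d in self.dogs],
            }
        )


def joint_from_marginals(
    vet: float, insured: float, kc: float, pets: float
) -> dict[tuple[int, int, int, int], float]:
    """Independent 16-cell joint table from four marginal probabilities."""
    marg = {"vet": vet, "insured": insured, "kc": kc, "pets": pets}
    for name, p in marg.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"marginal {name!r} must be in [0, 1]")
    table = {}
    for cell in itertools.product((0, 1), repeat=4):
        p = 1.0
        for bit, m in zip(cell, (vet, insured, kc, pets)):
            p *= m if bit else 1.0 - m
        table[cell] = p
    return table


@dataclass
class SurveyConfig:
    n_areas: int = 17
    calls_per_area: int = 100
    quota: int = 30
    p_valid: float = 0.37
    p_own: float = 0.24
    extra_dog_rate: float = 0.48
    area_effect_sd: float = 0.55
    membership_joint: Mapping[tuple[int, int, int, int], float] = field(
        default_factory=lambda: joint_from_marginals(0.72, 0.40, 0.30, 0.03)
    )
    household_flag_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_valid", "p_own", "household_flag_correlation"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if self.extra_dog_rate < 0:
            raise ConfigurationError("extra_dog_rate must be nonnegative")
        if self.area_effect_sd < 0:
            raise ConfigurationError("area_effect_sd must be nonnegative")
        if self.n_areas < 1 or self.calls_per_area < 1 or self.quota < 1:
            raise ConfigurationError("n_areas, calls_per_area and quota must be >= 1")
        total = float(sum(self.membership_joint.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"membership_joint must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in self.membership_joint.values()):
            raise ConfigurationError("membership_joint cells must be nonnegative")


def generate_survey(config: SurveyConfig) -> SurveyDataset:
    """Simulate a quota-style telephone survey (quota NOT yet applied)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = list(config.membership_joint.keys())
    cell_p = np.asarray([config.membership_joint[c] for c in cells], dtype=float)
    cell_p = cell_p / cell_p.sum()

    areas = [f"area{i + 1:02d}" for i in range(config.n_areas)]
    area_effects = rng.normal(0.0, config.area_effect_sd, size=config.n_areas)
    calls: list[CallRecord] = []
    dogs: list[DogRecord] = []
    for area, effect in zip(areas, area_effects):
        if config.p_own in (0.0, 1.0):
            p_own_area = config.p_own  # logit undefined at the endpoints
        else:
            p_own_area = float(expit(logit(config.p_own) + effect))
        for order in range(1, config.calls_per_area + 1):
            valid = bool(rng.random() < config.p_valid)
            n_dogs = 0
            if valid and rng.random() < p_own_area:
                n_dogs = 1 + int(rng.poisson(config.extra_dog_rate))
            call = CallRecord(area, order, valid, n_dogs)
            calls.append(call)
            if n_dogs:
                shared = cells[rng.choice(len(cells), p=cell_p)]
                for _ in range(n_dogs):
                    if rng.random() < config.household_flag_correlation:
                        cell = shared
                    else:
                        cell = cells[rng.choice(len(cells), p=cell_p)]
                    dogs.append(
                        DogRecord(call.household_id, area, *map(bool, cell))
                    )
    n_valid = sum(c.valid for c in calls)
    return SurveyDataset(areas, calls, dogs, len(calls), n_valid)


def generate_practice_sizes(mixture, n: int, seed: int | None = None) -> np.ndarray:
    """Draw per-practice registered-dog counts from a normal mixture.

    Draws are rounded to integers and truncated at 1: a normal mixture has
    negative support but a responding practice registers at least one dog.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    mixture.validate()
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0, dtype=int)
    comp = rng.choice(mixture.n_components, size=n, p=mixture.weights)
    raw = rng.normal(mixture.means[comp], mixture.sds[comp])
    return np.maximum(1, np.rint(raw)).astype(int)


def generate_registry(
    start_year: int,
    end_year: int,
    annual_counts_model: Callable[[int], float],
    survival=None,
    seed: int | None = None,
    noise: str | None = None,
):
    """Annual registration counts from a deterministic model, optionally with
    Poisson noise.  The survival curve is validated and attached for bundling
    with the series; attrition itself is applied downstream."""
    from .registry_survival import RegistrationSeries

    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    if survival is not None:
        survival.validate()
    rng = np.random.default_rng(seed)
    years = list(range(start_year, end_year + 1))
    counts = []
    for year in years:
        mean = float(annual_counts_model(year))
        if mean < 0:
            raise ValueError(f"counts model yields negative mean at {year}")
        if noise is None:
            counts.append(int(round(mean)))
        elif noise == "poisson":
            counts.append(int(rng.poisson(mean)))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    series = RegistrationSeries(np.asarray(years), np.asarray(counts))
    series.survival = survival
    return series


def synthetic_survival_curve():
    """Synthetic all-breed dog survival curve (stand-in, not published data).

    Shape emulates insured-dog survival studies: near-certain survival
    through mid-life, accelerating mortality from about age 8, essentially
    no survivors past 18.  The per-age variance grows with age, reflecting
    the thinning of old-age cohorts in the underlying actuarial data.
    """
    from .registry_survival import SurvivalCurve

    ages = np.arange(0, 19)
    survival = np.array(
        [0.98, 0.97, 0.96, 0.95, 0.93, 0.91, 0.88, 0.84, 0.79, 0.72,
         0.63, 0.52, 0.40, 0.28, 0.18, 0.10, 0.05, 0.02, 0.01]
    )
    sd = 0.01 + 0.004 * ages
    return SurvivalCurve(ages, survival, sd**2)


@dataclass
class BreedCountyConfig:
    breed_shares: Mapping[str, float]
    county_rows: Sequence[tuple[str, float, float, float]]  # name, share, km2, pop
    n_breed_total: int = 10_000
    n_county_total: int = 10_000
    sources: Sequence[str] = ("microchip",)

    def validate(self) -> None:
        if not self.breed_shares or not self.county_rows:
            raise ConfigurationError("need at least one breed and one county")
        for label, shares in (
            ("breed_shares", list(self.breed_shares.values())),
            ("county shares", [r[1] for r in self.county_rows]),
        ):
            if abs(sum(shares) - 1.0) > 1e-9 or any(s < 0 for s in shares):
                raise ConfigurationError(f"{label} must be nonnegative and sum to 1")


def generate_breed_county_tables(
    config: BreedCountyConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial breed and county count tables for the demographics stage."""
    config.validate()
    rng = np.random.default_rng(seed)
    breeds = list(config.breed_shares)
    shares = np.asarray([config.breed_shares[b] for b in breeds], dtype=float)
    breed_rows = []
    for source in config.sources:
        counts = rng.multinomial(config.n_breed_total, shares)
        breed_rows.extend(
            {"source": source, "breed": b, "count": int(c)}
            for b, c in zip(breeds, counts)
        )
    county_shares = np.asarray([r[1] for r in config.county_rows], dtype=float)
    county_counts = rng.multinomial(config.n_county_total, county_shares)
    county_rows = [
        {
            "county": name,
            "count": int(c),
            "area_km2": float(km2),
            "human_population": float(pop),
        }
        for (name, _, km2, pop), c in zip(config.county_rows, county_counts)
    ]
    return pd.DataFrame(breed_rows), pd.DataFrame(county_rows)


# ---------------------------------------------------------------------------
# In-study fixture: the published per-area survey table.
# ---------------------------------------------------------------------------

#: (area, printed response rate %, dog-owning households of 30, dogs).
TABLE3_AREAS: list[tuple[str, float, int, int]] = [
    ("Aberdeen and Shetland", 35.33, 12, 14),
    ("Bath and West Wiltshire", 29.70, 8, 10),
    ("Blackpool and the Fylde", 31.91, 4, 7),
    ("Bromley and Orpington", 38.46, 3, 3),
    ("Central and South Wales", 35.58, 20, 29),
    ("Cornwall and Isles of Scilly", 65.22, 10, 13),
    ("Durham and Wearside", 37.04, 4, 7),
    ("Glasgow South", 31.25, 7, 14),
    ("Hemel Hempstead", 60.00, 5, 7),
    ("Huddersfield", 51.72, 5, 7),
    ("Liverpool", 40.67, 7, 7),
    ("Manchester Central", 44.12, 3, 5),
    ("Milton Keynes", 37.04, 6, 11),
    ("Nottingham", 31.91, 8, 9),
    ("Salisbury", 33.71, 8, 16),
    ("Stratford-upon-Avon", 34.88, 6, 15),
    ("Walsall, Cannock and Lichfield", 30.41, 6, 7),
]

#: Membership counts out of 181 dogs.  Each is the unique integer k in 0..181
#: with round(100*k/181, 2) equal to the published two-decimal percentage
#: (71.82, 40.33, 30.39, 2.76) — confirmed by exhaustive search.
FIXTURE_MEMBERSHIP_COUNTS = {"vet": 130, "insured": 73, "kc": 55, "pets": 5}

#: Published call-volume totals the fixture reconstructs exactly.
FIXTURE_TOTAL_CALLS = 1656
FIXTURE_VALID_CALLS = 614


def _fixture_call_layout() -> list[tuple[str, int, int]]:
    """Per-area (valid calls, total calls) reconstruction.

    Only the per-area response rates, the 30-valid quota and the grand totals
    (614 valid of 1656 calls) are published.  Deterministic reconstruction:
    36 valid calls per area (+1 for the first two areas to reach 614), total
    calls = round(100*valid/rate), then invalid calls adjusted round-robin so
    the grand total is exactly 1656.
    """
    n_areas = len(TABLE3_AREAS)
    base = FIXTURE_VALID_CALLS // n_areas
    remainder = FIXTURE_VALID_CALLS - base * n_areas
    valid = [base + (1 if i < remainder else 0) for i in range(n_areas)]
    totals = [
        int(np.floor(100.0 * v / rate + 0.5))
        for v, (_, rate, _, _) in zip(valid, TABLE3_AREAS)
    ]
    deficit = FIXTURE_TOTAL_CALLS - sum(totals)
    step = 1 if deficit > 0 else -1
    i = 0
    while deficit != 0:
        if step > 0 or totals[i % n_areas] > valid[i % n_areas]:
            totals[i % n_areas] += step
            deficit -= step
        i += 1
    return [
        (area, v, t)
        for (area, _, _, _), v, t in zip(TABLE3_AREAS, valid, totals)
    ]


def paper_survey_fixture() -> SurveyDataset:
    """Deterministic reconstruction of the published survey.

    Per area: the published dog-owning household and dog counts are placed in
    the first valid calls (each owning household gets one dog plus extras
    distributed round-robin); further valid calls up to the reconstructed
    per-area volume are non-owning; remaining calls are invalid.  Dog-level
    flags follow a documented nesting convention: dogs are ordered by the
    published table's row order, then call order; the first 130 are
    vet-registered, the first 73 insured, the first 55 kennel-club registered
    and the first 5 travel-scheme registered — reproducing the published
    marginals exactly while keeping the (unpublished) overlap cells maximal.
    """
    layout = _fixture_call_layout()
    calls: list[CallRecord] = []
    household_dogs: list[tuple[str, str, int]] = []  # household, area, n_dogs
    for (area, _, owning, dogs_total), (_, n_valid, n_total) in zip(
        TABLE3_AREAS, layout
    ):
        per_household = [1] * owning
        for extra in range(dogs_total - owning):
            per_household[extra % owning] += 1
        for order in range(1, n_total + 1):
            if order <= owning:
                n_dogs = per_household[order - 1]
                valid = True
            elif order <= n_valid:
                n_dogs = 0
                valid = True
            else:
                n_dogs = 0
                valid = False
            call = CallRecord(area, order, valid, n_dogs)
            calls.append(call)
            if n_dogs:
                household_dogs.append((call.household_id, area, n_dogs))

    dogs: list[DogRecord] = []
    index = 0
    thresholds = FIXTURE_MEMBERSHIP_COUNTS
    for household, area, n_dogs in household_dogs:
        for _ in range(n_dogs):
            index += 1
            dogs.append(
                DogRecord(
                    household,
                    area,
                    vet=index <= thresholds["vet"],
                    insured=index <= thresholds["insured"],
                    kc=index <= thresholds["kc"],
                    pets_travel=index <= thresholds["pets"],
                )
            )
    areas = [row[0] for row in TABLE3_AREAS]
    return SurveyDataset(
        areas, calls, dogs, FIXTURE_TOTAL_CALLS, FIXTURE_VALID_CALLS
    )
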