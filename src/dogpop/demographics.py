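"""Breed and county demographics across registration sources.

Breed tables from different sources (microchip registry, an insurer's book,
kennel-club registrations) are normalised onto a canonical breed list,
ranked by share (competition ranking: ties take the smallest applicable
rank), and compared: a breed whose rank differs by at least a configurable
gap between two sources is flagged as over-/under-represented.  County
counts are converted into three share columns — raw, per-km2 adjusted, and
per-capita adjusted — each renormalised to 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BreedTable",
    "BreedComparison",
    "DEFAULT_BREED_MAPPING",
    "CANONICAL_BREEDS",
    "SPECIAL_ROWS",
    "REFERENCE_BREED_SHARES",
    "reference_breed_tables",
    "normalize_breeds",
    "rank_breeds",
    "compare_sources",
    "pct_change",
    "county_adjusted_shares",
]

#: Rows reported but excluded from ranking.
SPECIAL_ROWS = ("Unknown", "Cross")

#: Canonical breed labels recognised without mapping.  Covers the breeds of
#: the cross-source comparison tables; extend via the ``canonical`` argument
#: of :func:`normalize_breeds` for larger registries.
CANONICAL_BREEDS: frozenset[str] = frozenset(
    {
        "Retriever (Labrador)",
        "Staffordshire Bull Terrier",
        "German Shepherd Dog (Alsatian)",
        "Border Collie",
        "Spaniel (Cocker)",
        "Spaniel (English Springer)",
        "Yorkshire Terrier",
        "Retriever (Golden)",
        "West Highland White Terrier",
        "Cavalier King Charles Spaniel",
        "Rottweiler",
        "Border Terrier",
        "Shih Tzu",
        "Boxer",
        "Lhasa Apso",
        "Poodle",
        "Bichon Frise",
        "Greyhound",
        "Weimaraner",
        "Dalmatian",
        "Miniature Schnauzer",
        "Dachshund",
        "Bulldog",
        "Chihuahua",
        "Bull Terrier",
        "Whippet",
        "Pug",
        "King Charles Spaniel",
        "Jack Russell Terrier",
        "Beagle",
    }
)

#: Raw-name collapses onto canonical breed labels.  Covers the variant and
#: size-class names most often seen in registry exports; anything unmatched
#: that is not already canonical is pooled into Unknown.
DEFAULT_BREED_MAPPING: dict[str, str] = {
    "Toy Poodle": "Poodle",
    "Miniature Poodle": "Poodle",
    "Standard Poodle": "Poodle",
    "Labrador": "Retriever (Labrador)",
    "Labrador Retriever": "Retriever (Labrador)",
    "Golden Retriever": "Retriever (Golden)",
    "Alsatian": "German Shepherd Dog (Alsatian)",
    "German Shepherd": "German Shepherd Dog (Alsatian)",
    "Cocker Spaniel": "Spaniel (Cocker)",
    "English Springer Spaniel": "Spaniel (English Springer)",
    "Springer Spaniel": "Spaniel (English Springer)",
    "Jack Russell": "Jack Russell Terrier",
    "Staffie": "Staffordshire Bull Terrier",
    "Staffy": "Staffordshire Bull Terrier",
    "Westie": "West Highland White Terrier",
    "Crossbreed": "Cross",
    "Mongrel": "Cross",
    "Mixed Breed": "Cross",
}


#: Published cross-source breed shares (%) used as reference input for the
#: demographics stage: {breed: (microchip %, insurance %, kennel-club %,
#: % change in KC registrations 1999-2008)}.  None = not reported.
REFERENCE_BREED_SHARES: dict[str, tuple[float | None, ...]] = {
    "Unknown": (23.37, 2.73, None, None),
    "Cross": (12.60, 28.91, None, None),
    "Retriever (Labrador)": (9.96, 10.89, 16.40, 35.44),
    "Staffordshire Bull Terrier": (4.92, 3.75, 3.90, 8.53),
    "German Shepherd Dog (Alsatian)": (4.22, 3.60, 4.32, -33.52),
    "Border Collie": (4.21, 2.88, 0.86, 25.59),
    "Spaniel (Cocker)": (3.49, 5.65, 8.16, 68.25),
    "Spaniel (English Springer)": (3.39, 2.92, 5.40, 20.07),
    "Yorkshire Terrier": (2.49, 1.70, 1.43, -46.16),
    "Retriever (Golden)": (2.48, 3.54, 3.32, -28.05),
    "West Highland White Terrier": (2.48, 2.34, 2.66, -49.16),
    "Cavalier King Charles Spaniel": (2.01, 4.83, 4.07, -3.03),
    "Rottweiler": (1.57, 0.79, 0.95, -50.41),
    "Border Terrier": (1.46, 1.61, 3.32, 138.84),
    "Shih Tzu": (1.25, 1.25, 1.99, 45.33),
    "Boxer": (1.04, 0.89, 2.67, -25.68),
    "Lhasa Apso": (0.86, 0.68, 1.86, 61.22),
    "Poodle": (0.83, 0.88, 1.31, -0.66),
    "Bichon Frise": (0.70, 1.08, 1.00, 13.27),
    "Greyhound": (0.63, 0.33, 0.02, 17.95),
    "Weimaraner": (0.63, 0.91, 0.83, -4.75),
    "Dalmatian": (0.60, 0.76, 0.57, -40.99),
    "Miniature Schnauzer": (0.60, 1.00, 1.93, 142.19),
    "Dachshund": (0.60, 0.57, 1.98, 1.47),
    "Bulldog": (0.54, 0.78, 1.65, 115.72),
    "Chihuahua": (0.53, 0.39, 2.57, -18.80),
    "Bull Terrier": (0.49, 0.79, 1.06, 11.02),
    "Whippet": (0.48, 0.26, 1.21, 104.80),
    "Pug": (0.29, 0.59, 1.62, 524.83),
    "King Charles Spaniel": (0.28, 0.83, 0.07, -15.38),
}


def reference_breed_tables() -> list[BreedTable]:
    """The three published share tables as :class:`BreedTable` objects."""
    tables = []
    for idx, source in enumerate(("microchip", "insurance", "kc")):
        shares = {
            breed: row[idx]
            for breed, row in REFERENCE_BREED_SHARES.items()
            if row[idx] is not None
        }
        tables.append(BreedTable.from_counts(source, shares))
    return tables


@dataclass
class BreedTable:
    source: str
    data: pd.DataFrame  # columns: breed, count, share_pct

    def named(self) -> pd.DataFrame:
        """Rows eligible for ranking (Unknown/Cross excluded)."""
        return self.data[~self.data["breed"].isin(SPECIAL_ROWS)]

    @classmethod
    def from_counts(cls, source: str, counts: Mapping[str, float]) -> "BreedTable":
        df = pd.DataFrame(
            {"breed": list(counts), "count": [float(counts[b]) for b in counts]}
        )
        total = df["count"].sum()
        df["share_pct"] = 100.0 * df["count"] / total if total else 0.0
        return cls(source, df)


@dataclass
class BreedComparison:
    breed: str
    ranks: dict[str, int | None]
    shares: dict[str, float | None]
    flags: dict[tuple[str, str], str] = field(default_factory=dict)
    pct_change_kc: float | None = None


def normalize_breeds(
    raw_counts: Mapping[str, float],
    mapping: Mapping[str, str] | None = None,
    source: str = "source",
    canonical: frozenset[str] | set[str] | None = None,
) -> BreedTable:
    """Map raw breed names onto canonical labels and pool counts.

    Canonical labels (the mapping's values plus :data:`CANONICAL_BREEDS`)
    pass through unchanged, so the operation is idempotent; unmatched names
    are pooled into Unknown.  Counts are conserved exactly.
    """
    if not raw_counts:
        raise ValueError("empty breed table")
    mapping = DEFAULT_BREED_MAPPING if mapping is None else mapping
    known = set(mapping.values()) | set(SPECIAL_ROWS) | set(
        CANONICAL_BREEDS if canonical is None else canonical
    )
    pooled: dict[str, float] = {}
    for name, count in raw_counts.items():
        if name in mapping:
            target = mapping[name]
        elif name in known:
            target = name
        else:
            target = "Unknown"
        pooled[target] = pooled.get(target, 0.0) + float(count)
    return BreedTable.from_counts(source, pooled)


def rank_breeds(table: BreedTable) -> pd.Series:
    """Competition ranks (1 = largest share) over named breeds."""
    named = table.named()
    if named.empty:
        raise ValueError("no named breeds to rank")
    ranks = named.set_index("breed")["share_pct"].rank(
        method="min", ascending=False
    )
    return ranks.astype(int)


def compare_sources(
    tables: Sequence[BreedTable],
    rank_gap_threshold: int = 10,
    kc_changes: Mapping[str, float] | None = None,
) -> list[BreedComparison]:
    """Cross-source rank/share comparison with representation flags.

    For each ordered source pair (a, b), a breed is flagged
    ``over-represented`` in *a* when rank_a <= rank_b - threshold (it ranks
    at least ``threshold`` places higher in *a*), ``under`` in the mirror
    case, else ``neutral``.  Breeds absent from a source get no flag for
    pairs involving it.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 sources to compare")
    ranks = {t.source: rank_breeds(t) for t in tables}
    shares = {
        t.source: t.named().set_index("breed")["share_pct"] for t in tables
    }
    breeds = sorted(set().union(*(set(r.index) for r in ranks.values())))
    out = []
    sources = [t.source for t in tables]
    for breed in breeds:
        comp = BreedComparison(
            breed,
            {s: (int(ranks[s][breed]) if breed in ranks[s] else None) for s in sources},
            {s: (float(shares[s][breed]) if breed in shares[s] else None) for s in sources},
            pct_change_kc=(kc_changes or {}).get(breed),
        )
        for a in sources:
            for b in sources:
                if a >= b:
                    continue
                ra, rb = comp.ranks[a], comp.ranks[b]
                if ra is None or rb is None:
                    continue
                if ra <= rb - rank_gap_threshold:
                    comp.flags[(a, b)] = "over"
                elif rb <= ra - rank_gap_threshold:
                    comp.flags[(a, b)] = "under"
                else:
                    comp.flags[(a, b)] = "neutral"
        out.append(comp)
    return out


def pct_change(series: Mapping[int, float], y0: int, y1: int) -> float:
    """Percentage change in registrations between two years."""
    if y0 not in series or y1 not in series:
        raise ValueError("both years must be present in the series")
    base = series[y0]
    if base == 0:
        logger.warning("zero baseline in %s; percentage change undefined", y0)
        return float("nan")
    return 100.0 * (series[y1] - base) / base


def county_adjusted_shares(counties: pd.DataFrame) -> pd.DataFrame:
    """Raw, area-adjusted and population-adjusted county shares.

    ``counties`` needs columns county, count, area_km2, human_population.
    Unknown-county rows are excluded, as are rows with non-positive area or
    population (logged); each share column is renormalised to sum to 100
    over the retained rows.
    """
    df = counties.copy()
    unknown = df["county"].str.strip().str.lower() == "unknown"
    if unknown.any():
        logger.info("excluding %d unknown-county rows", int(unknown.sum()))
    df = df[~unknown]
    bad = (df["area_km2"] <= 0) | (df["human_population"] <= 0)
    if bad.any():
        logger.warning(
            "excluding %d rows with non-positive area or population", int(bad.sum())
        )
    df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable county rows")
    count = df["count"].astype(float)
    per_km2 = count / df["area_km2"]
    per_cap = count / df["human_population"]
    df["raw_share"] = 100.0 * count / count.sum()
    df["area_adjusted_share"] = 100.0 * per_km2 / per_km2.sum()
    df["population_adjusted_share"] = 100.0 * per_cap / per_cap.sum()
    return df
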