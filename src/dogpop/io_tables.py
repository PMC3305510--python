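"""Typed CSV I/O and run configuration.

All pipeline artifacts are plain UTF-8 CSVs with a header row and '.'
decimal separator.  Each table has a declared schema (column names and
types); violations are reported with the offending column and data row so a
malformed hand-edited input fails loudly rather than propagating NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import constants
from .synthetic_data import CallRecord, DogRecord, SurveyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_survey",
    "read_survey",
    "RunConfig",
]


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


#: table name -> {column: numpy-compatible dtype}
SCHEMAS: dict[str, dict[str, type]] = {
    "survey_calls": {"area_id": str, "call_order": int, "valid": int, "n_dogs": int},
    "survey_dogs": {
        "household_id": str,
        "area_id": str,
        "vet": int,
        "insured": int,
        "kc": int,
        "pets": int,
    },
    "practices": {"practice_id": str, "n_dogs": int},
    "registrations": {"year": int, "count": int},
    "survival": {"age_years": int, "survival": float, "variance": float},
    "breeds": {"source": str, "breed": str, "count": int},
    "counties": {
        "county": str,
        "count": int,
        "area_km2": float,
        "human_population": float,
    },
}


def read_table(path: str | Path, schema: str | Mapping[str, type]) -> pd.DataFrame:
    """Read and validate a CSV against a schema (by name or mapping)."""
    spec = SCHEMAS[schema] if isinstance(schema, str) else dict(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    out = pd.DataFrame(index=df.index)
    for column, dtype in spec.items():
        raw = df[column]
        if dtype is str:
            out[column] = raw
            continue
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & (raw.str.strip() != "")
        empty = raw.str.strip() == ""
        if bad.any() or empty.any():
            row = int((bad | empty).idxmax()) + 2  # 1-based + header line
            raise SchemaError(
                f"{path}: column {column!r} has a malformed value at line {row}"
            )
        if dtype is int:
            if not np.allclose(converted, np.round(converted)):
                row = int((converted != np.round(converted)).idxmax()) + 2
                raise SchemaError(
                    f"{path}: column {column!r} expects integers (line {row})"
                )
            out[column] = converted.astype(int)
        else:
            out[column] = converted.astype(float)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    calls = write_table(dataset.calls_frame(), out_dir / "survey_calls.csv")
    dogs = write_table(dataset.dogs_frame(), out_dir / "survey_dogs.csv")
    return calls, dogs


def read_survey(
    calls_path: str | Path,
    dogs_path: str | Path,
    n_total_calls: int | None = None,
    n_valid_calls: int | None = None,
) -> SurveyDataset:
    calls_df = read_table(calls_path, "survey_calls")
    dogs_df = read_table(dogs_path, "survey_dogs")
    calls = [
        CallRecord(r.area_id, int(r.call_order), bool(r.valid), int(r.n_dogs))
        for r in calls_df.itertuples()
    ]
    dogs = [
        DogRecord(
            r.household_id,
            r.area_id,
            bool(r.vet),
            bool(r.insured),
            bool(r.kc),
            bool(r.pets),
        )
        for r in dogs_df.itertuples()
    ]
    areas = list(dict.fromkeys(c.area_id for c in calls))
    if n_total_calls is None:
        n_total_calls = len(calls)
        n_valid_calls = sum(c.valid for c in calls)
    return SurveyDataset(areas, calls, dogs, n_total_calls, n_valid_calls)


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    The constants block mirrors the analysis' fixed inputs so every one of
    them can be overridden and is logged when used.
    """

    seed: int = 0
    out_dir: str = "dogpop_out"
    quota: int = constants.SURVEY_QUOTA
    n_boot: int = 10_000
    use_fixture: bool = True
    mcmc: dict = field(
        default_factory=lambda: {
            "n_iterations": 100_000,
            "burn_in": 10_000,
            "thin": 50,
            "n_chains": 2,
        }
    )
    constants: dict = field(
        default_factory=lambda: {
            "n_households": constants.N_HOUSEHOLDS,
            "n_practices": constants.N_PRACTICES,
            "practices_per_response": constants.PRACTICES_PER_RESPONSE,
            "effective_practices": constants.EFFECTIVE_PRACTICES,
            "n_practice_responses": constants.N_PRACTICE_RESPONSES,
            "insured_subpop": constants.INSURED_SUBPOP,
            "kc_subpop_mean": constants.KC_SUBPOP_MEAN,
            "kc_subpop_sd": constants.KC_SUBPOP_SD,
            "murray_prior_mean": constants.MURRAY_PRIOR_MEAN,
            "murray_prior_sd": constants.MURRAY_PRIOR_SD,
        }
    )
    mixture_k: int = 3
    mixture_restarts: int = 20
    reference_year: int = 2009

    def validate(self) -> None:
        for name, value in self.constants.items():
            if not value > 0:
                raise ValueError(f"constant {name} must be positive (got {value})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        config = cls()
        for key, value in data.items():
            if not hasattr(config, key):
                raise SchemaError(f"unknown configuration key {key!r}")
            if isinstance(getattr(config, key), dict) and isinstance(value, dict):
                getattr(config, key).update(value)
            else:
                setattr(config, key, value)
        config.validate()
        return config

    def log_constants(self) -> None:
        for name, value in sorted(self.constants.items()):
            logger.info("constant %s = %s", name, value)
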