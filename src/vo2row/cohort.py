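"""Athlete/cohort data model and delimited-text I/O.

A :class:`RowerRecord` holds one athlete's anthropometric and
rowing-ergometer variables together with the measured maximal oxygen
uptake (VO2max, absolute mL·min⁻¹).  A :class:`Cohort` is an ordered
collection of records with unique athlete ids, typically a "development"
or "validation" group of one sex.

Cohorts are read and written as comma-separated UTF-8 text with a
mandatory header.  The column schema (documented in the README) is::

    athlete_id, sex, age_yr, body_mass_kg, height_cm, fat_pct,
    lean_body_mass_kg, distance_4min_m, stroke_rate_spm, mean_power_w,
    hr_max_bpm, vo2max_ml_min

``lean_body_mass_kg`` and ``vo2max_ml_min`` are optional on input: lean
body mass is derived from body mass and body-fat percentage when absent,
and VO2max may be missing for prediction-only use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RowerRecord",
    "Cohort",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "cohort_moments",
    "COLUMN_OF",
    "NUMERIC_FIELDS",
]

log = logging.getLogger(__name__)

#: record field -> CSV column name (fixed order defines the file layout)
COLUMN_OF = {
    "athlete_id": "athlete_id",
    "sex": "sex",
    "age": "age_yr",
    "body_mass": "body_mass_kg",
    "height": "height_cm",
    "fat_pct": "fat_pct",
    "lean_body_mass": "lean_body_mass_kg",
    "distance_4min": "distance_4min_m",
    "stroke_rate": "stroke_rate_spm",
    "mean_power": "mean_power_w",
    "hr_max": "hr_max_bpm",
    "vo2max_measured": "vo2max_ml_min",
}

NUMERIC_FIELDS = (
    "age",
    "body_mass",
    "height",
    "fat_pct",
    "lean_body_mass",
    "distance_4min",
    "stroke_rate",
    "mean_power",
    "hr_max",
    "vo2max_measured",
)

#: columns that must appear in every cohort file
_MANDATORY_COLUMNS = tuple(
    COLUMN_OF[f]
    for f in COLUMN_OF
    if f not in ("lean_body_mass", "vo2max_measured")
)

_SEXES = ("male", "female")


class SchemaError(ValueError):
    """A cohort file does not conform to the documented CSV schema."""


@dataclass(frozen=True)
class RowerRecord:
    """One athlete's anthropometric and ergometer variables.

    All physical quantities are strictly positive; ``fat_pct`` is the
    body-fat percentage of body mass (0–60); ``lean_body_mass`` must be
    smaller than ``body_mass``.  ``vo2max_measured`` (absolute VO2max in
    mL·min⁻¹) is optional so that records can be used for
    prediction-only workflows.
    """

    athlete_id: str
    sex: str
    age: float
    body_mass: float
    height: float
    fat_pct: float
    lean_body_mass: float
    distance_4min: float
    stroke_rate: float
    mean_power: float
    hr_max: float
    vo2max_measured: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(
                f"record {self.athlete_id!r}: sex must be one of {_SEXES}, got {self.sex!r}"
            )
        for name in NUMERIC_FIELDS:
            value = getattr(self, name)
            if value is None:
                if name == "vo2max_measured":
                    continue
                raise ValueError(f"record {self.athlete_id!r}: {name} is required")
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"record {self.athlete_id!r}: {name} must be finite and > 0, got {value!r}"
                )
        if not 0 < self.fat_pct < 60:
            raise ValueError(
                f"record {self.athlete_id!r}: fat_pct must lie in (0, 60), got {self.fat_pct!r}"
            )
        if self.lean_body_mass >= self.body_mass:
            raise ValueError(
                f"record {self.athlete_id!r}: lean_body_mass ({self.lean_body_mass}) "
                f"must be smaller than body_mass ({self.body_mass})"
            )

    @property
    def vo2max_relative(self) -> Optional[float]:
        """Mass-relative VO2max (mL·kg⁻¹·min⁻¹); derived convenience only."""
        if self.vo2max_measured is None:
            return None
        return self.vo2max_measured / self.body_mass


@dataclass(frozen=True)
class Cohort:
    """An ordered, id-unique collection of :class:`RowerRecord`."""

    records: tuple[RowerRecord, ...]
    label: str = ""
    sex_filter: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.athlete_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate athlete_id in cohort: {dupes}")
        if self.sex_filter is not None:
            bad = [r.athlete_id for r in self.records if r.sex != self.sex_filter]
            if bad:
                raise ValueError(
                    f"cohort declares sex_filter={self.sex_filter!r} but records "
                    f"{bad} have a different sex"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RowerRecord]:
        return iter(self.records)

    def values(self, field_name: str) -> np.ndarray:
        """All non-missing values of one numeric field, in record order."""
        if field_name not in NUMERIC_FIELDS:
            raise KeyError(f"unknown numeric field {field_name!r}")
        vals = [getattr(r, field_name) for r in self.records]
        return np.asarray([v for v in vals if v is not None], dtype=float)

    def ids(self) -> tuple[str, ...]:
        return tuple(r.athlete_id for r in self.records)

    def subset(self, ids: Iterable[str], label: str = "") -> "Cohort":
        """Sub-cohort containing exactly the given ids, in cohort order."""
        wanted = set(ids)
        missing = wanted - set(self.ids())
        if missing:
            raise KeyError(f"ids not in cohort: {sorted(missing)}")
        recs = tuple(r for r in self.records if r.athlete_id in wanted)
        return Cohort(recs, label=label or self.label, sex_filter=self.sex_filter)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame with the documented CSV column names."""
        rows = {
            col: [getattr(r, f) for r in self.records] for f, col in COLUMN_OF.items()
        }
        return pd.DataFrame(rows, columns=list(COLUMN_OF.values()))


def cohort_moments(cohort: Cohort, field_name: str) -> tuple[float, float]:
    """Sample mean and sample SD (n−1 denominator) of one numeric field.

    Mirrors the descriptive "mean ± SD" convention used throughout the
    reporting; requires at least two non-missing values.
    """
    vals = cohort.values(field_name)
    if vals.size < 2:
        raise ValueError(
            f"field {field_name!r} has {vals.size} value(s); need ≥2 for moments"
        )
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def _parse_numeric(raw: str, column: str, row_number: int) -> Optional[float]:
    text = raw.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(
            f"row {row_number}: column {column!r} has non-numeric value {raw!r}"
        ) from None


def read_cohort(path: str | Path, delimiter: str = ",", label: str = "") -> Cohort:
    """Read a cohort CSV, validating it against the documented schema.

    Header matching is case-insensitive.  ``lean_body_mass_kg`` may be
    absent or empty; it is then derived as ``body_mass · (1 − fat_pct/100)``.
    When both a supplied and a derivable lean body mass exist and they
    disagree by more than 0.1 kg, the supplied value wins and a warning
    summarising the mismatches is logged (measured data beats derivation).

    Raises :class:`SchemaError` for a missing mandatory column or a
    non-numeric cell (with its row number), and :class:`ValueError` for
    duplicate athlete ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]

    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    has_lbm = COLUMN_OF["lean_body_mass"] in df.columns
    has_vo2 = COLUMN_OF["vo2max_measured"] in df.columns

    records = []
    lbm_mismatches = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_dict = dict(zip(df.columns, row))
        kwargs: dict = {
            "athlete_id": row_dict[COLUMN_OF["athlete_id"]].strip(),
            "sex": row_dict[COLUMN_OF["sex"]].strip().lower(),
        }
        for f in NUMERIC_FIELDS:
            col = COLUMN_OF[f]
            if col not in df.columns:
                kwargs[f] = None
                continue
            kwargs[f] = _parse_numeric(row_dict[col], col, i)

        derived = kwargs["body_mass"] * (1 - kwargs["fat_pct"] / 100.0)
        if not has_lbm or kwargs["lean_body_mass"] is None:
            kwargs["lean_body_mass"] = derived
        elif abs(kwargs["lean_body_mass"] - derived) > 0.1:
            lbm_mismatches += 1
        if not has_vo2:
            kwargs["vo2max_measured"] = None
        records.append(RowerRecord(**kwargs))

    if lbm_mismatches:
        log.warning(
            "%s: supplied lean_body_mass disagrees with body_mass·(1−fat_pct/100) "
            "by >0.1 kg for %d of %d records; supplied values kept",
            path,
            lbm_mismatches,
            len(records),
        )
    return Cohort(tuple(records), label=label or path.stem)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text with the documented column order.

    Floats are written at full round-tripping precision (Python's
    shortest-repr), so ``read_cohort(write_cohort(c)) == c`` exactly.
    Missing optional values are written as empty cells.  An empty cohort
    is an error.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    df = cohort.to_frame()
    df.to_csv(path, sep=delimiter, index=False, na_rep="")
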