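"""Read, validate and write long-format NCD mortality tables.

The pipeline consumes mortality estimates shaped like a Global Burden of
Disease (GBD) results-tool export: one row per (country, WHO region, sex,
year, 5-year age group, cause) carrying a death count and a mortality rate,
for the four major noncommunicable diseases used in premature-NCD
monitoring — cardiovascular disease, cancer, chronic obstructive pulmonary
disease and diabetes mellitus.

Internally all rates are stored in the canonical unit *deaths per
person-year*; files may declare "per1000" or "per100000" and are rescaled on
read and write.  Age groups are half-open five-year bands [x, x+5) with
x in {30, 35, ..., 85}; the label ``"30-34"`` denotes [30, 35).
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_STARTS",
    "CAUSES",
    "CAUSE_CODES",
    "COLUMNS",
    "CompletenessError",
    "CompletenessReport",
    "DataError",
    "Dataset",
    "GBD_COLUMN_MAP",
    "InconsistencyError",
    "MortalityRecord",
    "RATE_UNITS",
    "SEXES",
    "SchemaError",
    "UNDEFINED_POPULATION",
    "ValidationError",
    "WHO_REGIONS",
    "implied_population",
    "read_mortality_table",
    "write_mortality_table",
]

#: GBD cause codes for the four major NCDs of the premature-mortality metric.
CAUSE_CODES: Mapping[str, int] = {
    "cardiovascular disease": 410,
    "cancer": 587,
    "chronic obstructive pulmonary disease": 491,
    "diabetes mellitus": 509,
}
CAUSES: tuple[str, ...] = tuple(CAUSE_CODES)
_CODE_TO_CAUSE = {str(code): name for name, code in CAUSE_CODES.items()}
# common label variants accepted on input
_CAUSE_ALIASES = {
    "cvd": "cardiovascular disease",
    "copd": "chronic obstructive pulmonary disease",
    "diabetes": "diabetes mellitus",
    "diabetes mellitus": "diabetes mellitus",
    "neoplasms": "cancer",
}

WHO_REGIONS: tuple[str, ...] = (
    "African",
    "Americas",
    "South-East Asia",
    "European",
    "Eastern Mediterranean",
    "Western Pacific",
)
SEXES: tuple[str, ...] = ("female", "male")
AGE_STARTS: tuple[int, ...] = tuple(range(30, 90, 5))
N_AGE_GROUPS = len(AGE_STARTS)
N_CAUSES = len(CAUSES)

#: declared unit -> divisor that converts a printed value to per person-year
RATE_UNITS: Mapping[str, float] = {
    "person-year": 1.0,
    "per1000": 1_000.0,
    "per100000": 100_000.0,
}

COLUMNS: tuple[str, ...] = (
    "country", "region", "sex", "year", "age_group", "cause", "deaths", "rate",
)
_KEY_COLUMNS = ("country", "sex", "year", "age_group", "cause")

#: rename map for a raw GBD results-tool export header
GBD_COLUMN_MAP: Mapping[str, str] = {
    "location": "country",
    "age": "age_group",
    "val": "rate",
}

#: explicit marker for a 0/0 population (zero deaths at zero rate)
UNDEFINED_POPULATION = float("nan")


class DataError(ValueError):
    """Base class for mortality-table input problems."""


class SchemaError(DataError):
    """A required column is missing or unmappable."""


class ValidationError(DataError):
    """A row violates a value constraint (sign, vocabulary, duplicate key)."""


class CompletenessError(DataError):
    """A stratum is missing one or more required (age, cause) cells."""


class InconsistencyError(DataError):
    """Deaths reported at zero rate — no finite population can explain it."""


@dataclass(frozen=True)
class MortalityRecord:
    """One (country, region, sex, year, age group, cause) mortality cell.

    ``rate`` is in the canonical unit, deaths per person-year; ``age_group``
    is the lower bound x of the half-open band [x, x+5).
    """

    country: str
    region: str
    sex: str
    year: int
    age_group: int
    cause: str
    deaths: float
    rate: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_STARTS:
            raise ValidationError(f"age group start {self.age_group} outside 30..85 grid")
        if self.cause not in CAUSES:
            raise ValidationError(f"unknown cause {self.cause!r}")
        if not (self.deaths >= 0):
            raise ValidationError(f"negative deaths {self.deaths}")
        if not (self.rate >= 0) or not math.isfinite(self.rate):
            raise ValidationError(f"rate {self.rate} is negative or non-finite")


@dataclass(frozen=True)
class CompletenessReport:
    """Expected versus present key count for a loaded table."""

    expected: int
    present: int

    @property
    def fraction(self) -> float:
        return self.present / self.expected if self.expected else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.present}/{self.expected} cells present ({self.percent:.1f}%)"


@dataclass
class Dataset:
    """A validated long-format mortality table in canonical units.

    ``frame`` has the columns in :data:`COLUMNS` with ``age_group`` as the
    integer lower bound and ``rate`` in deaths per person-year.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing columns {missing}")
        self.frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def completeness(self) -> CompletenessReport:
        f = self.frame
        expected = (
            f["country"].nunique() * f["sex"].nunique() * f["year"].nunique()
            * N_AGE_GROUPS * N_CAUSES
        )
        return CompletenessReport(expected=expected, present=len(f))

    def records(self) -> Iterator[MortalityRecord]:
        for row in self.frame.itertuples(index=False):
            yield MortalityRecord(
                country=row.country, region=row.region, sex=row.sex,
                year=int(row.year), age_group=int(row.age_group),
                cause=row.cause, deaths=float(row.deaths), rate=float(row.rate),
            )


_AGE_RE = re.compile(r"^\s*(\d+)\s*(?:[-–]|to)\s*(\d+)")


def _parse_age(value) -> int:
    """Return the lower bound of a 5-year band from an int or a label."""
    if isinstance(value, (int, np.integer)):
        x = int(value)
    elif isinstance(value, float) and value.is_integer():
        x = int(value)
    else:
        m = _AGE_RE.match(str(value))
        if m is None:
            raise ValidationError(f"unparseable age group {value!r}")
        x, hi = int(m.group(1)), int(m.group(2))
        if hi not in (x + 4, x + 5):
            raise ValidationError(f"age group {value!r} is not a 5-year band")
    if x not in AGE_STARTS:
        raise ValidationError(f"age group start {x} outside the 30..85 grid")
    return x


def _normalize_cause(value) -> str:
    s = str(value).strip().lower()
    if s in CAUSE_CODES:
        return s
    if s in _CAUSE_ALIASES:
        return _CAUSE_ALIASES[s]
    code = s.removesuffix(".0")
    if code in _CODE_TO_CAUSE:
        return _CODE_TO_CAUSE[code]
    raise ValidationError(
        f"unknown cause {value!r}; expected one of {list(CAUSES)} or codes "
        f"{sorted(CAUSE_CODES.values())}"
    )


def _normalize_sex(value) -> str:
    s = str(value).strip().lower()
    if s in SEXES:
        return s
    raise ValidationError(f"unknown sex {value!r}; expected female or male")


def _rate_divisor(rate_unit: str) -> float:
    if rate_unit not in RATE_UNITS:
        raise ValueError(f"unknown rate unit {rate_unit!r}; choose from {list(RATE_UNITS)}")
    return RATE_UNITS[rate_unit]


def read_mortality_table(
    path,
    rate_unit: str = "person-year",
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Dataset:
    """Read and validate a delimited mortality table.

    Parameters
    ----------
    path
        Delimited text file (comma default, tab accepted) with one header row.
    rate_unit
        Unit the file's ``rate`` column is expressed in; values are rescaled
        to deaths per person-year on load.
    sep
        Field delimiter; autodetected between comma and tab if ``None``.
    column_map
        Optional rename map from file headers to the canonical schema, e.g.
        :data:`GBD_COLUMN_MAP` for a raw results-tool export.

    Raises
    ------
    SchemaError
        If a required column is absent after applying ``column_map``.
    ValidationError
        On negative deaths/rates, unknown vocabulary or duplicate keys.
    """
    path = Path(path)
    divisor = _rate_divisor(rate_unit)
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype={"country": str, "region": str})
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path.name}")

    frame = pd.DataFrame(
        {
            "country": raw["country"].astype(str),
            "region": raw["region"].astype(str),
            "sex": [_normalize_sex(v) for v in raw["sex"]],
            "year": pd.to_numeric(raw["year"], errors="raise").astype(int),
            "age_group": [_parse_age(v) for v in raw["age_group"]],
            "cause": [_normalize_cause(v) for v in raw["cause"]],
            "deaths": pd.to_numeric(raw["deaths"], errors="raise").astype(float),
            "rate": pd.to_numeric(raw["rate"], errors="raise").astype(float),
        }
    )

    bad = frame.index[(frame["deaths"] < 0) | (frame["rate"] < 0)]
    if len(bad):
        raise ValidationError(f"negative deaths or rate at file row(s) {list(bad[:5])}")
    bad = frame.index[~np.isfinite(frame["rate"])]
    if len(bad):
        raise ValidationError(f"non-finite rate at file row(s) {list(bad[:5])}")

    dup = frame.duplicated(subset=list(_KEY_COLUMNS), keep=False)
    if dup.any():
        keys = frame.loc[dup, list(_KEY_COLUMNS)].drop_duplicates().head(5)
        raise ValidationError(
            "duplicate (country, sex, year, age_group, cause) key(s): "
            + "; ".join(str(tuple(r)) for r in keys.itertuples(index=False))
        )

    frame["rate"] = frame["rate"] / divisor
    ds = Dataset(frame=frame, provenance=provenance or str(path))
    rep = ds.completeness
    logger.info("loaded %s: %s", path.name, rep)
    return ds


def write_mortality_table(
    dataset: Dataset,
    path,
    rate_unit: str = "person-year",
    sep: str = ",",
):
    """Write a dataset as delimited text, rescaling rates to ``rate_unit``.

    Round-trips with :func:`read_mortality_table`: reading the file back with
    the same declared unit reproduces the canonical rates to full float
    precision (values are printed with 17 significant digits).
    """
    divisor = _rate_divisor(rate_unit)
    out = dataset.frame.copy()
    out["age_group"] = [f"{x}-{x + 4}" for x in out["age_group"]]
    out["rate"] = out["rate"] * divisor
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def implied_population(deaths, rate=None, rate_unit: str = "person-year") -> float:
    """Population implied by a death count and a mortality rate.

    With the rate per 1 000 this is deaths × 1000 / rate; in canonical units
    it reduces to deaths / rate.  Accepts a :class:`MortalityRecord` or a
    (deaths, rate) pair.

    Returns :data:`UNDEFINED_POPULATION` (NaN) when deaths and rate are both
    zero — an explicit marker, never a silent 0/0.

    Raises
    ------
    InconsistencyError
        If deaths are positive at zero rate.
    """
    if isinstance(deaths, MortalityRecord):
        record = deaths
        deaths, rate = record.deaths, record.rate
    if rate is None:
        raise TypeError("rate is required when deaths is not a MortalityRecord")
    rate_py = rate / _rate_divisor(rate_unit)  # per person-year
    if deaths < 0 or rate_py < 0:
        raise ValidationError("deaths and rate must be non-negative")
    if rate_py == 0:
        if deaths == 0:
            return UNDEFINED_POPULATION
        raise InconsistencyError(f"{deaths} deaths reported at zero mortality rate")
    return deaths / rate_py
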