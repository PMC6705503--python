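"""WHO life-table metric for premature and older NCD mortality.

Computational core of the package.  For each (population unit, sex, year)
stratum the four cause-specific mortality rates are summed into twelve
age-specific rates 5Mx (x = 30, 35, ..., 85), converted to interval death
probabilities with the WHO NCD-monitoring life-table formula

    5qx = 5 * 5Mx / (1 + 2.5 * 5Mx),

and chained into two unconditional probabilities of death:

    40q30 = 1 - prod_{x=30..65} (1 - 5qx)   (premature, ages 30-69)
    20q70 = 1 - prod_{x=70..85} (1 - 5qx)   (older, ages 70-89)

The older:premature ratio 20q70 / 40q30 is the comparison statistic.
Products are accumulated in ascending-age order; at these magnitudes (at
most twelve factors well away from underflow) no log-space rework is needed.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gbd_io import (
    AGE_STARTS,
    N_AGE_GROUPS,
    N_CAUSES,
    CompletenessError,
    DataError,
    Dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AgeSchedule",
    "MAX_RATE",
    "MetricInstance",
    "OLDER_AGES",
    "PREMATURE_AGES",
    "compute_metrics",
    "metrics_to_frame",
    "rate_to_prob",
    "sum_causes",
    "unconditional_prob",
]

#: eight 5-year groups spanning ages 30-69
PREMATURE_AGES: tuple[int, ...] = tuple(range(30, 70, 5))
#: four 5-year groups spanning ages 70-89
OLDER_AGES: tuple[int, ...] = tuple(range(70, 90, 5))

#: rate above which the conversion formula would exceed 1 (5m/(1+2.5m) = 1 at m = 0.4)
MAX_RATE = 0.4


@dataclass(frozen=True)
class AgeSchedule:
    """Twelve summed all-four-cause rates 5Mx for one (unit, sex, year)."""

    unit: str
    sex: str
    year: int
    m: np.ndarray  # per person-year, ascending x = 30..85

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (N_AGE_GROUPS,):
            raise DataError(f"age schedule needs {N_AGE_GROUPS} entries, got {m.shape}")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise DataError("age-specific rates must be finite and non-negative")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class MetricInstance:
    """40q30, 20q70 and their ratio for one (unit, sex, year) stratum.

    ``ratio`` is NaN when 40q30 is zero (undefined; excluded from medians
    and fits downstream).
    """

    unit: str
    sex: str
    year: int
    q5: np.ndarray  # twelve 5qx, ascending age
    q40_30: float
    q20_70: float
    ratio: float


def rate_to_prob(m):
    """Convert 5-year mortality rate(s) 5Mx to death probability(ies) 5qx.

    Applies 5qx = 5m / (1 + 2.5m), the WHO life-table conversion used for
    the premature-NCD mortality metric.  Accepts a scalar or array; rates
    above 0.4 (where the formula exceeds one) are clamped to probability 1
    with a logged warning, never returned silently above 1.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0):
        raise DataError("mortality rate must be non-negative")
    q = 5.0 * arr / (1.0 + 2.5 * arr)
    over = arr > MAX_RATE
    if np.any(over):
        n = int(np.count_nonzero(over))
        logger.warning("%d rate(s) exceed %.1f; clamping 5qx to 1", n, MAX_RATE)
        warnings.warn(f"{n} rate(s) exceed {MAX_RATE}; 5qx clamped to 1", stacklevel=2)
        q = np.minimum(q, 1.0)
    return q if np.ndim(m) else float(q)


def unconditional_prob(q5, x_from: int, x_to: int, ages: Sequence[int] | None = None) -> float:
    """Probability of dying in [x_from, x_to) given survival to x_from.

    ``q5`` holds 5-year probabilities 5qx; if it is a plain sequence it is
    assumed to start at age 30 in 5-year steps (a pandas Series may carry its
    own age index).  Returns 1 - prod(1 - 5qx) over the covered groups —
    eight groups for 40q30, four for 20q70.
    """
    if ages is None:
        if isinstance(q5, pd.Series):
            ages = [int(a) for a in q5.index]
        else:
            ages = list(range(30, 30 + 5 * len(q5), 5))
    q = np.asarray(q5, dtype=float)
    if len(ages) != len(q):
        raise DataError("ages and q5 have different lengths")
    if x_from % 5 or x_to % 5 or x_to <= x_from:
        raise DataError(f"window [{x_from}, {x_to}) not aligned to the 5-year grid")
    if np.any(q < 0) or np.any(q > 1):
        raise DataError("5qx entries must lie in [0, 1]")
    lookup = dict(zip(ages, q))
    needed = range(x_from, x_to, 5)
    missing = [x for x in needed if x not in lookup]
    if missing:
        raise DataError(f"q5 does not cover age group(s) {missing}")
    surv = 1.0
    for x in needed:  # ascending age
        surv *= 1.0 - lookup[x]
    return 1.0 - surv


def sum_causes(dataset: Dataset, unit: str, sex: str, year: int) -> AgeSchedule:
    """Sum the four cause-specific rates into the stratum's 5Mx schedule.

    Requires all 48 (12 age x 4 cause) cells; a missing cell is an error,
    never imputed.
    """
    f = dataset.frame
    sub = f[(f["country"] == unit) & (f["sex"] == sex) & (f["year"] == year)]
    counts = sub.groupby("age_group")["rate"].count()
    missing = [
        (x, int(counts.get(x, 0))) for x in AGE_STARTS if counts.get(x, 0) != N_CAUSES
    ]
    if missing:
        cells = ", ".join(f"age {x} has {n}/{N_CAUSES} causes" for x, n in missing)
        raise CompletenessError(f"stratum ({unit}, {sex}, {year}) incomplete: {cells}")
    m = sub.groupby("age_group")["rate"].sum().reindex(AGE_STARTS).to_numpy()
    return AgeSchedule(unit=unit, sex=sex, year=year, m=m)


def _metrics_from_m(m: np.ndarray):
    """Vectorised 40q30 / 20q70 / ratio from an (n, 12) matrix of 5Mx."""
    q = rate_to_prob(m)
    n_prem = len(PREMATURE_AGES)
    q40 = 1.0 - np.prod(1.0 - q[:, :n_prem], axis=1)
    q20 = 1.0 - np.prod(1.0 - q[:, n_prem:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q40 > 0, q20 / np.where(q40 > 0, q40, 1.0), np.nan)
    return q, q40, q20, ratio


def compute_metrics(dataset: Dataset) -> list[MetricInstance]:
    """Compute one :class:`MetricInstance` per (unit, sex, year) stratum.

    Every stratum must be complete (48 cells); on the full 195-country,
    2-sex, 6-year design this yields exactly 2 340 instances.  Strata with
    40q30 = 0 are emitted with ratio NaN and counted in the log.
    """
    f = dataset.frame
    keys = ["country", "sex", "year"]
    counts = f.pivot_table(index=keys, columns="age_group", values="rate", aggfunc="count")
    counts = counts.reindex(columns=AGE_STARTS)
    bad = counts.isna() | (counts != N_CAUSES)
    if bad.to_numpy().any():
        idx = np.argwhere(bad.to_numpy())[0]
        unit, sex, year = counts.index[idx[0]]
        age = counts.columns[idx[1]]
        raise CompletenessError(
            f"stratum ({unit}, {sex}, {year}) missing cause cell(s) at age {age}"
        )
    rates = f.pivot_table(index=keys, columns="age_group", values="rate", aggfunc="sum")
    rates = rates.reindex(columns=AGE_STARTS)
    m = rates.to_numpy()
    q, q40, q20, ratio = _metrics_from_m(m)
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        logger.info("%d stratum/strata with 40q30 = 0: ratio undefined", n_undef)
    out = []
    for i, (unit, sex, year) in enumerate(rates.index):
        out.append(
            MetricInstance(
                unit=str(unit), sex=str(sex), year=int(year), q5=q[i],
                q40_30=float(q40[i]), q20_70=float(q20[i]), ratio=float(ratio[i]),
            )
        )
    return out


def metrics_to_frame(instances: Iterable[MetricInstance]) -> pd.DataFrame:
    """Tabulate metric instances (full precision, no rounding)."""
    rows = [
        (mi.unit, mi.sex, mi.year, mi.q40_30, mi.q20_70, mi.ratio)
        for mi in instances
    ]
    return pd.DataFrame(rows, columns=["unit", "sex", "year", "q40_30", "q20_70", "ratio"])
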