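"""Descriptive summaries: band-level death/rate tables and metric distributions.

Two reporting surfaces:

* a two-band summary table (premature, ages 30-69 vs older, ages 70-89) of
  deaths, column percentages and crude rates per 1 000, broken down by year,
  sex, WHO region and cause; and
* distribution statistics (median, labelled extremes, n) for 40q30, 20q70
  and the older:premature ratio, optionally grouped.

All internal statistics are kept at full precision; half-up rounding happens
only at the reporting layer.  Medians use the midpoint-of-two convention for
even n.  Extreme-value labels are tie-broken lexicographically on
(unit, sex, year) so reports are deterministic.
"""
from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import cell_populations
from .gbd_io import DataError, Dataset
from .lifetable import MetricInstance, OLDER_AGES, PREMATURE_AGES, metrics_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "distribution_stats",
    "proportion",
    "round_half_up",
    "table1_summary",
]

BANDS = {
    "premature (30-69)": PREMATURE_AGES,
    "older (70-89)": OLDER_AGES,
}

_STATISTICS = ("q40_30", "q20_70", "ratio")


def round_half_up(x: float, dp: int) -> float:
    """Round half away from zero at ``dp`` decimals (reporting convention)."""
    if not np.isfinite(x):
        return float("nan")
    exp = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def proportion(numerator: int, denominator: int, dp: int = 1) -> float:
    """Percentage 100*numerator/denominator, rounded half-up to ``dp``."""
    if denominator <= 0:
        raise DataError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DataError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, dp)


def _block(sub: pd.DataFrame, pops: pd.DataFrame, category: str, level: str,
           band_deaths: float, pop_override: float | None = None) -> dict:
    """One summary row: deaths, % of band, crude rate per 1 000."""
    deaths = float(sub["deaths"].sum())
    if pop_override is not None:
        pop = pop_override
    else:
        cells = sub.drop_duplicates(subset=["country", "sex", "year", "age_group"])
        idx = cells.set_index(["country", "sex", "year", "age_group"]).index
        pop = float(np.nansum(idx.map(pops["population"]).to_numpy(dtype=float)))
    rate = deaths * 1000.0 / pop if pop > 0 else float("nan")
    return {
        "category": category,
        "level": level,
        "deaths": deaths,
        "population": pop,
        "deaths_millions": round_half_up(deaths / 1e6, 2),
        "pct_of_band": round_half_up(100.0 * deaths / band_deaths, 1) if band_deaths > 0 else float("nan"),
        "rate_per_1000": round_half_up(rate, 2),
    }


def table1_summary(dataset: Dataset) -> pd.DataFrame:
    """Deaths and crude mortality by band, year, sex, region and cause.

    For each band the rate is total deaths x 1000 over the summed implied
    population of the contributing (country, sex, year, age-group) cells.
    Cause rows share the band's whole population denominator (the four
    causes apply to the same people); percentages are column percentages
    relative to the band total.  Blocks whose population cannot be derived
    get a missing (NaN) rate, never a silent zero.
    """
    f = dataset.frame
    pops = cell_populations(f)
    rows = []
    for band, ages in BANDS.items():
        sub = f[f["age_group"].isin(ages)]
        total = _block(sub, pops, "total", "total", band_deaths=float(sub["deaths"].sum()))
        band_deaths = total["deaths"]
        band_pop = total["population"]
        rows.append({"band": band, **total})
        for year in sorted(sub["year"].unique()):
            rows.append({"band": band, **_block(sub[sub["year"] == year], pops, "year", str(year), band_deaths)})
        for sex in sorted(sub["sex"].unique()):
            rows.append({"band": band, **_block(sub[sub["sex"] == sex], pops, "sex", sex, band_deaths)})
        for region in sorted(sub["region"].unique()):
            rows.append({"band": band, **_block(sub[sub["region"] == region], pops, "region", region, band_deaths)})
        for cause in sorted(sub["cause"].unique()):
            rows.append({"band": band, **_block(sub[sub["cause"] == cause], pops, "cause", cause,
                                                band_deaths, pop_override=band_pop)})
    return pd.DataFrame(rows)


def _as_frame(instances) -> pd.DataFrame:
    if isinstance(instances, pd.DataFrame):
        return instances
    return metrics_to_frame(instances)


def distribution_stats(
    instances: Iterable[MetricInstance] | pd.DataFrame,
    by: str | None = None,
) -> pd.DataFrame:
    """Median, labelled min/max and n for each metric, optionally grouped.

    ``by`` may be ``"sex"``, ``"year"`` or ``"unit"`` (use unit-level region
    instances for a by-region breakdown).  Undefined ratios (NaN) are
    excluded, with ``n`` reflecting the exclusion; empty groups are omitted
    with a logged warning.  Min/max labels are the (unit, sex, year) of the
    extreme instance, ties broken lexicographically.
    """
    frame = _as_frame(instances)
    if by is not None and by not in ("sex", "year", "unit"):
        raise ValueError("by must be one of None, 'sex', 'year', 'unit'")
    groups = [("overall", frame)] if by is None else [
        (str(k), g) for k, g in frame.groupby(by, sort=True)
    ]
    rows = []
    for gname, g in groups:
        for stat in _STATISTICS:
            sub = g[np.isfinite(g[stat])]
            if sub.empty:
                logger.warning("group %s has no defined %s values; omitted", gname, stat)
                continue
            # lexicographic label order breaks value ties deterministically
            s = sub.sort_values([stat, "unit", "sex", "year"], kind="mergesort")
            lo = s.iloc[0]
            hi_val = s[stat].iloc[-1]
            hi = s[s[stat] == hi_val].iloc[0]
            rows.append(
                {
                    "statistic": stat,
                    "group": gname,
                    "n": int(len(sub)),
                    "median": float(sub[stat].median()),
                    "min": float(lo[stat]),
                    "min_label": (lo["unit"], lo["sex"], int(lo["year"])),
                    "max": float(hi[stat]),
                    "max_label": (hi["unit"], hi["sex"], int(hi["year"])),
                }
            )
    return pd.DataFrame(rows)
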