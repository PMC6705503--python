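"""Merge country strata into WHO regions or a global total.

Regional data are derived by merging member-country data: deaths are summed
exactly, each country's population is implied from its own deaths and rate
(deaths x 1000 / rate per 1000, i.e. deaths / rate in per-person-year
units), and the merged rate is total deaths over total implied population —
a population-weighted mean of the member rates.

Population is derived per (country, sex, year, age-group) cell from the
cause-summed deaths and cause-summed rate, since the four causes share one
population.  Cells with zero deaths and zero rate have no derivable
population; they contribute zero deaths and are excluded from the
population sum with a logged count.
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .gbd_io import Dataset, InconsistencyError, DataError
from .lifetable import MetricInstance, compute_metrics

logger = logging.getLogger(__name__)

__all__ = ["cell_populations", "merge_units", "region_metrics", "global_metrics"]

_CELL_KEYS = ["country", "sex", "year", "age_group"]


def cell_populations(frame: pd.DataFrame) -> pd.DataFrame:
    """Implied population per (country, sex, year, age-group) cell.

    Returns a frame indexed by the cell keys with columns ``deaths`` (cause
    total), ``rate`` (cause-summed, per person-year) and ``population``
    (deaths/rate; NaN where both are zero).

    Raises
    ------
    InconsistencyError
        If any cell has positive deaths at zero summed rate.
    """
    g = frame.groupby(_CELL_KEYS, sort=True).agg(
        deaths=("deaths", "sum"), rate=("rate", "sum")
    )
    bad = (g["rate"] == 0) & (g["deaths"] > 0)
    if bad.any():
        key = g.index[bad][0]
        raise InconsistencyError(
            f"cell {key} reports {g.loc[key, 'deaths']} deaths at zero rate"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pop = np.where(g["rate"] > 0, g["deaths"] / g["rate"], np.nan)
    g["population"] = pop
    n_undef = int(np.isnan(pop).sum())
    if n_undef:
        logger.info("%d zero-death cell(s) with undefined population excluded", n_undef)
    return g


def merge_units(dataset: Dataset, grouping: Mapping[str, str]) -> Dataset:
    """Merge countries into groups per the country -> group map.

    Per (group, sex, year, age-group, cause): deaths are summed and the rate
    is total deaths over total implied member population.  The result is a
    valid Dataset whose ``country`` (and ``region``) column holds the group
    labels.
    """
    f = dataset.frame
    unmapped = sorted(set(f["country"]) - set(grouping))
    if unmapped:
        raise DataError(f"countries missing from the grouping map: {unmapped[:5]}")
    pops = cell_populations(f)

    f = f.copy()
    f["group"] = f["country"].map(grouping)
    pop_by_cell = f.set_index(_CELL_KEYS).index.map(pops["population"])
    f["cell_population"] = np.asarray(pop_by_cell, dtype=float)

    gkeys = ["group", "sex", "year", "age_group"]
    # population counted once per cell, not once per cause row
    cellpop = (
        f.drop_duplicates(subset=_CELL_KEYS)
        .groupby(gkeys, sort=True)["cell_population"]
        .sum(min_count=1)  # NaN-skipping; all-NaN -> NaN
    )
    deaths = f.groupby(gkeys + ["cause"], sort=True)["deaths"].sum()

    merged = deaths.reset_index()
    merged["population"] = merged.set_index(gkeys).index.map(cellpop).to_numpy(dtype=float)
    pop = merged["population"].to_numpy()
    d = merged["deaths"].to_numpy()
    rate = np.zeros(len(merged))
    has_pop = np.isfinite(pop) & (pop > 0)
    rate[has_pop] = d[has_pop] / pop[has_pop]
    if np.any(~has_pop & (d > 0)):
        row = merged[~has_pop & (merged["deaths"] > 0)].iloc[0]
        raise InconsistencyError(
            f"group stratum {tuple(row[gkeys])} has deaths but no derivable population"
        )
    merged["rate"] = rate

    out = pd.DataFrame(
        {
            "country": merged["group"],
            "region": merged["group"],
            "sex": merged["sex"],
            "year": merged["year"].astype(int),
            "age_group": merged["age_group"].astype(int),
            "cause": merged["cause"],
            "deaths": merged["deaths"].astype(float),
            "rate": merged["rate"].astype(float),
        }
    )
    return Dataset(frame=out, provenance=f"merged({dataset.provenance})")


def region_metrics(
    dataset: Dataset,
    region_map: Mapping[str, str] | None = None,
    include_global: bool = False,
) -> list[MetricInstance]:
    """Life-table metrics for WHO regions (and optionally the global total).

    ``region_map`` defaults to the dataset's own region column.  On the full
    design this yields 6 regions x 2 sexes x 6 years = 72 instances, plus 12
    global ones if requested.
    """
    if region_map is None:
        f = dataset.frame
        region_map = dict(zip(f["country"], f["region"]))
    merged = merge_units(dataset, region_map)
    instances = compute_metrics(merged)
    if include_global:
        instances += global_metrics(dataset)
    return instances


def global_metrics(dataset: Dataset) -> list[MetricInstance]:
    """Metrics for all countries merged into a single "global" unit."""
    grouping = {c: "global" for c in dataset.frame["country"].unique()}
    return compute_metrics(merge_units(dataset, grouping))
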