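"""Seeded generator of GBD-shaped mortality datasets with known ground truth.

Emulates the statistical structure of a Global Burden of Disease
results-tool export for the four major NCDs: age-increasing hazards, a male
excess, a mild downward secular trend, country-level heterogeneity, and a
cause composition dominated by cardiovascular disease and cancer.  The full
default design — 195 countries x 2 sexes x 12 age groups x 6 years x 4
causes — yields 112 320 records and 2 340 (country, sex, year) strata.

The hazard model is Gompertz on the log scale, evaluated at the interval
midpoint x + 2.5:

    m(x) = exp(alpha_sex + beta_sex * (x + 2.5 - 30)) * frailty_country
           * trend^period * cause_share

Per-country frailties are lognormal(0, sd^2) multipliers drawn in fixed
country order from a single seeded generator, so output is byte-identical
across runs with the same seed.  Deaths are deterministic rounds of
rate x population by default (keeping the file-based pipeline exactly equal
to the closed-form oracle); a Poisson option exists for robustness tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gbd_io import AGE_STARTS, CAUSES, DataError, Dataset, SEXES, WHO_REGIONS
from .lifetable import MAX_RATE, MetricInstance

__all__ = ["ScenarioConfig", "generate", "ground_truth_metrics", "scenario_from_yaml"]


def _default_population_by_age() -> dict[int, float]:
    # persons per country/sex cell; shrinks with age like a real pyramid
    return {x: 100_000.0 * 0.93 ** ((x - 30) / 5) for x in AGE_STARTS}


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic mortality surface.

    Defaults reproduce the study design (195 countries, both sexes, six
    5-year time points 1992-2017) with hazards whose premature and older
    band rates sit near a few and a few tens of deaths per 1 000 people
    respectively, a male excess, and a cause split led by cardiovascular
    disease and cancer.
    """

    n_countries: int = 195
    sexes: tuple[str, ...] = SEXES
    years: tuple[int, ...] = (1992, 1997, 2002, 2007, 2012, 2017)
    #: log-hazard at age 30 (interval midpoint 32.5), per sex
    gompertz_alpha: Mapping[str, float] = field(
        default_factory=lambda: {"female": -7.5, "male": -7.1}
    )
    #: log-hazard slope per year of age, per sex
    gompertz_beta: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.082, "male": 0.082}
    )
    #: sd of per-country lognormal frailty (0 -> identical countries)
    country_frailty_sd: float = 0.35
    #: multiplicative secular decline per 5-year step (<1 means improvement)
    trend_per_period: float = 0.96
    #: shares of the four causes, CVD-and-cancer dominated, summing to 1
    cause_split: tuple[float, ...] = (0.507, 0.372, 0.077, 0.044)
    #: persons per (age group) cell per country and sex
    population_by_age: Mapping[int, float] = field(default_factory=_default_population_by_age)
    seed: int = 2017
    #: draw Poisson deaths instead of deterministic rounding
    poisson_deaths: bool = False

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise DataError("need at least one country")
        split = np.asarray(self.cause_split, dtype=float)
        if len(split) != len(CAUSES) or np.any(split < 0):
            raise DataError("cause_split must be four non-negative shares")
        if abs(float(split.sum()) - 1.0) > 1e-12:
            raise DataError(f"cause_split sums to {split.sum()!r}, not 1")
        years = np.asarray(self.years)
        if len(years) > 1 and len(set(np.diff(years))) != 1:
            raise DataError("years must form an arithmetic sequence")
        for s in self.sexes:
            if s not in self.gompertz_alpha or s not in self.gompertz_beta:
                raise DataError(f"missing Gompertz parameters for sex {s!r}")
        missing_ages = [x for x in AGE_STARTS if x not in self.population_by_age]
        if missing_ages:
            raise DataError(f"population_by_age missing age group(s) {missing_ages}")

    def country_names(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_countries)]

    def country_regions(self) -> dict[str, str]:
        # round-robin assignment over the six WHO regions
        return {
            name: WHO_REGIONS[i % len(WHO_REGIONS)]
            for i, name in enumerate(self.country_names())
        }


def scenario_from_yaml(path) -> ScenarioConfig:
    """Build a config from a plain-text key-value (YAML) file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("sexes", "years", "cause_split"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "population_by_age" in raw:
        raw["population_by_age"] = {int(k): float(v) for k, v in raw["population_by_age"].items()}
    return ScenarioConfig(**raw)


def _country_frailties(config: ScenarioConfig) -> np.ndarray:
    """Per-country multipliers, drawn first from the seeded stream.

    Normal draws are truncated at +/-3 sd before exponentiation so that a
    single extreme country cannot push a hazard past the rate-to-probability
    conversion's 0.4 domain bound under the default scenario, whatever the
    seed.
    """
    rng = np.random.default_rng(config.seed)
    if config.country_frailty_sd == 0:
        # keep the stream position identical to the stochastic case
        rng.normal(size=config.n_countries)
        return np.ones(config.n_countries)
    z = np.clip(rng.normal(size=config.n_countries), -3.0, 3.0)
    return np.exp(config.country_frailty_sd * z)


def _total_hazard_surface(config: ScenarioConfig) -> np.ndarray:
    """All-four-cause rates, shape (countries, sexes, years, ages)."""
    frailty = _country_frailties(config)
    ages = np.asarray(AGE_STARTS, dtype=float)
    mid_offset = ages + 2.5 - 30.0
    n_y = len(config.years)
    base = np.empty((len(config.sexes), n_y, len(ages)))
    for si, sex in enumerate(config.sexes):
        alpha = config.gompertz_alpha[sex]
        beta = config.gompertz_beta[sex]
        for yi in range(n_y):
            base[si, yi] = np.exp(alpha + beta * mid_offset) * config.trend_per_period ** yi
    return frailty[:, None, None, None] * base[None, :, :, :]


def _check_hazard_bound(config: ScenarioConfig, m: np.ndarray) -> None:
    if np.any(m > MAX_RATE):
        ci, si, yi, ai = np.argwhere(m > MAX_RATE)[0]
        raise DataError(
            "config drives rate above "
            f"{MAX_RATE} at (country {config.country_names()[ci]}, "
            f"sex {config.sexes[si]}, year {config.years[yi]}, age {AGE_STARTS[ai]}): "
            f"m = {m[ci, si, yi, ai]:.4f}"
        )


def generate(config: ScenarioConfig) -> Dataset:
    """Generate the full long-format dataset for the configured design.

    One record per (country, sex, year, age group, cause); rates in deaths
    per person-year; deaths = round(rate x population) unless
    ``poisson_deaths`` is set.  Fully reproducible from ``config.seed``.
    """
    m_total = _total_hazard_surface(config)
    _check_hazard_bound(config, m_total)
    countries = config.country_names()
    regions = config.country_regions()
    split = np.asarray(config.cause_split, dtype=float)
    pop = np.asarray([config.population_by_age[x] for x in AGE_STARTS], dtype=float)

    # rates per cause, shape (country, sex, year, age, cause)
    rate = m_total[..., None] * split
    expected_deaths = rate * pop[None, None, None, :, None]
    if config.poisson_deaths:
        rng = np.random.default_rng(config.seed)
        rng.normal(size=config.n_countries)  # frailty draws come first in the stream
        deaths = rng.poisson(expected_deaths).astype(float)
    else:
        deaths = np.rint(expected_deaths)

    shape = rate.shape
    idx = np.indices(shape).reshape(len(shape), -1)
    frame = pd.DataFrame(
        {
            "country": np.asarray(countries)[idx[0]],
            "region": np.asarray([regions[c] for c in countries])[idx[0]],
            "sex": np.asarray(config.sexes)[idx[1]],
            "year": np.asarray(config.years)[idx[2]],
            "age_group": np.asarray(AGE_STARTS)[idx[3]],
            "cause": np.asarray(CAUSES)[idx[4]],
            "deaths": deaths.ravel(),
            "rate": rate.ravel(),
        }
    )
    return Dataset(frame=frame, provenance=f"synthetic(seed={config.seed})")


def ground_truth_metrics(config: ScenarioConfig) -> list[MetricInstance]:
    """Closed-form 40q30, 20q70 and ratio straight from the hazard model.

    No file round trip, no cause split-and-resum, and no shared code with
    the life-table module's vectorised path: the arithmetic is written out
    here independently so it can serve as the oracle against which the
    file-based pipeline is compared in tests.
    """
    m_total = _total_hazard_surface(config)
    _check_hazard_bound(config, m_total)
    countries = config.country_names()
    out: list[MetricInstance] = []
    for ci, country in enumerate(countries):
        for si, sex in enumerate(config.sexes):
            for yi, year in enumerate(config.years):
                m = m_total[ci, si, yi]
                q = np.array([min(5.0 * mi / (1.0 + 2.5 * mi), 1.0) for mi in m])
                surv_prem = 1.0
                for qi in q[:8]:
                    surv_prem *= 1.0 - qi
                surv_old = 1.0
                for qi in q[8:]:
                    surv_old *= 1.0 - qi
                q40 = 1.0 - surv_prem
                q20 = 1.0 - surv_old
                ratio = q20 / q40 if q40 > 0 else float("nan")
                out.append(
                    MetricInstance(unit=country, sex=sex, year=int(year), q5=q,
                                   q40_30=q40, q20_70=q20, ratio=ratio)
                )
    return out
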