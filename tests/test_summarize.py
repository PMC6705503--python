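"""Descriptive table, distribution statistics and proportion arithmetic."""
import numpy as np
import pandas as pd
import pytest

from ncdratio import Dataset, MetricInstance, distribution_stats, proportion, table1_summary
from ncdratio.gbd_io import AGE_STARTS, DataError
from ncdratio.lifetable import OLDER_AGES, PREMATURE_AGES
from ncdratio.summarize import round_half_up

_COLS = ["country", "region", "sex", "year", "age_group", "cause", "deaths", "rate"]


def _mi(unit, sex, year, ratio, q40=0.2, q20=0.6):
    q5 = np.full(12, 0.05)
    return MetricInstance(unit=unit, sex=sex, year=year, q5=q5,
                          q40_30=q40, q20_70=q20, ratio=ratio)


def _band_dataset(cause_deaths, band_rate_per_1000, ages, sex="female",
                  year=2017, country="World", region="European"):
    """Spread each cause's deaths uniformly over a band at a constant rate."""
    rows = []
    n = len(ages)
    total = sum(cause_deaths.values())
    for x in ages:
        for cause, d in cause_deaths.items():
            # cause-specific rate proportional to its death share
            rate = (band_rate_per_1000 / 1000.0) * (d / total)
            rows.append((country, region, sex, year, x, cause, d / n, rate))
    return pd.DataFrame(rows, columns=_COLS)


@pytest.mark.parametrize(
    "num, den, expected",
    [(4_364, 29_911, 14.6), (7_862, 68_518, 11.5), (0, 100, 0.0)],
)
def test_proportion_matches_printed_values(num, den, expected):
    assert proportion(num, den, dp=1) == expected


def test_proportion_domain_errors():
    with pytest.raises(DataError):
        proportion(1, 0)
    with pytest.raises(DataError):
        proportion(5, 4)


def test_round_half_up_at_the_tie():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.5, 0) == 3.0


def test_distribution_stats_median_conventions():
    odd = [_mi("A", "female", 2017, r) for r in (3.0, 1.0, 2.0)]
    even = odd + [_mi("B", "female", 2017, 4.0)]
    s_odd = distribution_stats(odd).set_index("statistic")
    s_even = distribution_stats(even).set_index("statistic")
    assert s_odd.loc["ratio", "median"] == 2.0
    assert s_even.loc["ratio", "median"] == 2.5
    assert s_odd.loc["ratio", "min"] == 1.0
    assert s_odd.loc["ratio", "max"] == 3.0


def test_distribution_stats_permutation_invariant():
    mis = [_mi(f"C{i}", "male", 2012, float(i)) for i in range(1, 8)]
    a = distribution_stats(mis)
    b = distribution_stats(list(reversed(mis)))
    pd.testing.assert_frame_equal(a, b)


def test_distribution_stats_excludes_undefined_ratios():
    mis = [_mi("A", "female", 2017, 2.0), _mi("B", "female", 2017, float("nan"))]
    s = distribution_stats(mis).set_index("statistic")
    assert s.loc["ratio", "n"] == 1
    assert s.loc["q40_30", "n"] == 2


def test_distribution_stats_labels_and_grouping():
    mis = [
        _mi("A", "female", 1992, 2.0),
        _mi("B", "female", 1997, 5.0),
        _mi("A", "male", 1992, 3.0),
    ]
    s = distribution_stats(mis, by="sex")
    ratio_f = s[(s.statistic == "ratio") & (s.group == "female")].iloc[0]
    assert ratio_f["min_label"] == ("A", "female", 1992)
    assert ratio_f["max_label"] == ("B", "female", 1997)


def test_distribution_stats_tie_break_is_lexicographic():
    mis = [_mi("B", "female", 2017, 2.0), _mi("A", "female", 2017, 2.0)]
    s = distribution_stats(mis).set_index("statistic")
    assert s.loc["ratio", "min_label"] == ("A", "female", 2017)
    assert s.loc["ratio", "max_label"] == ("A", "female", 2017)


def test_table1_single_cause_block_is_100_percent():
    frame = _band_dataset({"cancer": 1_000_000.0}, 4.0, PREMATURE_AGES)
    t = table1_summary(Dataset(frame=frame))
    cause = t[(t.category == "cause")]
    assert list(cause["pct_of_band"]) == [100.0]


def test_table1_two_equal_years_split_50_50():
    f1 = _band_dataset({"cancer": 1e6}, 4.0, PREMATURE_AGES, year=2012)
    f2 = _band_dataset({"cancer": 1e6}, 4.0, PREMATURE_AGES, year=2017)
    t = table1_summary(Dataset(frame=pd.concat([f1, f2], ignore_index=True)))
    years = t[t.category == "year"]
    assert list(years["pct_of_band"]) == [50.0, 50.0]


def test_table1_reproduces_2017_band_cells():
    """A dataset built to the 2017 global deaths/rates prints the same cells.

    Premature band: 12.55 million deaths at 3.72 per 1000; older band:
    16.15 million at 39.22 per 1000 (synthetic single-stratum stand-in).
    """
    prem = _band_dataset({"cardiovascular disease": 12.55e6}, 3.72, PREMATURE_AGES)
    old = _band_dataset({"cardiovascular disease": 16.15e6}, 39.22, OLDER_AGES)
    t = table1_summary(Dataset(frame=pd.concat([prem, old], ignore_index=True)))
    tot = t[t.category == "total"].set_index("band")
    assert tot.loc["premature (30-69)", "deaths_millions"] == 12.55
    assert tot.loc["premature (30-69)", "rate_per_1000"] == 3.72
    assert tot.loc["older (70-89)", "deaths_millions"] == 16.15
    assert tot.loc["older (70-89)", "rate_per_1000"] == 39.22
    assert tot.loc["premature (30-69)", "pct_of_band"] == 100.0


def test_table1_cause_percentage_arithmetic():
    """32.10M of 63.33M band deaths rounds to the printed 50.7%."""
    frame = _band_dataset(
        {"cardiovascular disease": 32.10e6, "cancer": 31.23e6}, 3.93, PREMATURE_AGES
    )
    t = table1_summary(Dataset(frame=frame))
    cvd = t[(t.category == "cause") & (t.level == "cardiovascular disease")].iloc[0]
    assert cvd["pct_of_band"] == 50.7


def test_table1_percentages_close_per_block(small_dataset):
    t = table1_summary(small_dataset)
    for (band, cat), block in t[t.category != "total"].groupby(["band", "category"]):
        assert block["pct_of_band"].sum() == pytest.approx(100.0, abs=0.3)


def test_table1_synthetic_band_rates_are_ordered(small_dataset):
    t = table1_summary(small_dataset)
    tot = t[t.category == "total"].set_index("band")["rate_per_1000"]
    assert tot["older (70-89)"] > tot["premature (30-69)"]  # age gradient
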