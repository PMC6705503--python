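"""Life-table conversion, unconditional probabilities and metric instances."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ncdratio import (
    Dataset,
    compute_metrics,
    rate_to_prob,
    sum_causes,
    unconditional_prob,
)
from ncdratio.gbd_io import AGE_STARTS, CAUSES, CompletenessError, DataError
from ncdratio.lifetable import AgeSchedule, MAX_RATE


def _stratum_frame(rates_by_age, country="A", sex="female", year=2017,
                   cause_split=(0.25, 0.25, 0.25, 0.25)):
    """One complete (country, sex, year) stratum with the given total rates."""
    rows = []
    for x in AGE_STARTS:
        total = rates_by_age[x]
        for cause, share in zip(CAUSES, cause_split):
            rows.append((country, "European", sex, year, x, cause,
                         total * share * 1000.0, total * share))
    return pd.DataFrame(rows, columns=["country", "region", "sex", "year",
                                       "age_group", "cause", "deaths", "rate"])


@pytest.mark.parametrize("m, expected", [(0.0, 0.0), (0.4, 1.0), (0.02, 0.1 / 1.05)])
def test_rate_to_prob_closed_form(m, expected):
    assert rate_to_prob(m) == pytest.approx(expected, abs=1e-15)


def test_rate_to_prob_rejects_negative_and_clamps_high():
    with pytest.raises(DataError):
        rate_to_prob(-0.01)
    with pytest.warns(UserWarning, match="clamped"):
        assert rate_to_prob(0.5) == 1.0


def test_rate_to_prob_matches_constant_hazard_for_small_rates():
    """For m <= 0.01 the conversion tracks 1 - exp(-5m) to within 1e-4."""
    m = np.linspace(0.0, 0.01, 201)
    np.testing.assert_allclose(rate_to_prob(m), 1.0 - np.exp(-5.0 * m), atol=1e-4)


@given(st.floats(0.0, MAX_RATE), st.floats(0.0, MAX_RATE))
def test_rate_to_prob_monotone(m1, m2):
    lo, hi = sorted((m1, m2))
    assert rate_to_prob(lo) <= rate_to_prob(hi)


def test_unconditional_prob_boundaries():
    assert unconditional_prob([0.0] * 12, 30, 90) == 0.0
    q = [0.1] * 12
    q[3] = 1.0
    assert unconditional_prob(q, 30, 70) == 1.0


def test_unconditional_prob_eight_constant_groups():
    assert unconditional_prob([0.05] * 8, 30, 70) == pytest.approx(
        0.33657956871093775, rel=1e-14
    )


def test_unconditional_prob_respects_series_age_index():
    q = pd.Series(0.1, index=list(range(30, 90, 5)))
    assert unconditional_prob(q, 70, 90) == pytest.approx(1.0 - 0.9**4, rel=1e-14)


def test_unconditional_prob_window_errors():
    with pytest.raises(DataError):
        unconditional_prob([0.1] * 12, 32, 70)  # off-grid
    with pytest.raises(DataError):
        unconditional_prob([0.1] * 4, 30, 70)  # window not covered


@given(
    st.lists(st.floats(0.0, 0.9), min_size=8, max_size=8),
    st.integers(0, 7),
    st.floats(0.001, 0.09),
)
def test_unconditional_prob_monotone_in_each_q(qs, idx, bump):
    base = unconditional_prob(qs, 30, 70)
    higher = list(qs)
    higher[idx] = min(1.0, higher[idx] + bump)
    assert unconditional_prob(higher, 30, 70) >= base - 1e-15


def test_sum_causes_adds_four_rates():
    rates = {x: 0.004 for x in AGE_STARTS}
    sched = sum_causes(Dataset(frame=_stratum_frame(rates)), "A", "female", 2017)
    np.testing.assert_allclose(sched.m, 0.004, rtol=1e-12)
    # uneven split at one age: hand sum 0.002+0.001+0.0005+0.0001
    frame = _stratum_frame(rates)
    mask = frame["age_group"] == 30
    frame.loc[mask, "rate"] = [0.002, 0.001, 0.0005, 0.0001]
    sched = sum_causes(Dataset(frame=frame), "A", "female", 2017)
    assert sched.m[0] == pytest.approx(0.0036, rel=1e-12)


def test_sum_causes_zero_rates():
    sched = sum_causes(
        Dataset(frame=_stratum_frame({x: 0.0 for x in AGE_STARTS})), "A", "female", 2017
    )
    np.testing.assert_array_equal(sched.m, np.zeros(12))


def test_sum_causes_missing_cell_is_error():
    frame = _stratum_frame({x: 0.004 for x in AGE_STARTS})
    frame = frame[~((frame["age_group"] == 55) & (frame["cause"] == "cancer"))]
    with pytest.raises(CompletenessError, match="55"):
        sum_causes(Dataset(frame=frame), "A", "female", 2017)


def test_age_schedule_requires_twelve_entries():
    with pytest.raises(DataError):
        AgeSchedule("A", "female", 2017, np.zeros(11))


def test_compute_metrics_minimal_design_and_derived_values():
    """Constant 0.004 premature / 0.04 older rates hit the frozen chain values."""
    rates = {x: (0.004 if x < 70 else 0.04) for x in AGE_STARTS}
    [mi] = compute_metrics(Dataset(frame=_stratum_frame(rates)))
    assert mi.q40_30 == pytest.approx(0.14786075606124793, rel=1e-12)
    assert mi.q20_70 == pytest.approx(0.5518748719349773, rel=1e-12)
    assert mi.ratio == pytest.approx(3.7323958475254635, rel=1e-12)


def test_compute_metrics_counts_strata(small_dataset, small_config):
    mets = compute_metrics(small_dataset)
    assert len(mets) == small_config.n_countries * 2 * len(small_config.years)


def test_compute_metrics_recomputable_from_stored_q5(small_dataset):
    for mi in compute_metrics(small_dataset):
        q40 = 1.0 - np.prod(1.0 - mi.q5[:8])
        q20 = 1.0 - np.prod(1.0 - mi.q5[8:])
        assert abs(q40 - mi.q40_30) <= 1e-12
        assert abs(q20 - mi.q20_70) <= 1e-12


def test_compute_metrics_incomplete_stratum_is_error(small_dataset):
    frame = small_dataset.frame.iloc[:-1]
    with pytest.raises(CompletenessError):
        compute_metrics(Dataset(frame=frame))


def test_zero_premature_mortality_gives_undefined_ratio():
    rates = {x: (0.0 if x < 70 else 0.04) for x in AGE_STARTS}
    [mi] = compute_metrics(Dataset(frame=_stratum_frame(rates)))
    assert mi.q40_30 == 0.0
    assert math.isnan(mi.ratio)
    assert mi.q20_70 > 0
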