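"""Effect measures from 2x2 counts and the Statistic mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ebmkit as e
from ebmkit.errors import EstimateError, UndefinedMeasureError
from ebmkit.statistics import render_percent
from tests.conftest import random_estimate

WALKTHROUGH_TABLE = e.TwoByTwoCounts(939, 232, 801, 247)


def test_walkthrough_percentages_render_exactly():
    assert render_percent(e.compute_proportion(939, 1171).point) == "80.2%"
    assert render_percent(e.compute_proportion(801, 1048).point) == "76.4%"
    assert render_percent(e.compute_proportion(0, 100).point) == "0.0%"


def test_proportion_basics():
    est = e.compute_proportion(939, 1171)
    assert est.point == pytest.approx(939 / 1171)
    assert 0 <= est.ci_low <= est.point <= est.ci_high <= 1
    with pytest.raises(UndefinedMeasureError):
        e.compute_proportion(1, 0)
    with pytest.raises(ValueError):
        e.compute_proportion(5, 4)


def test_wilson_interval_against_hand_formula():
    # direct Wilson algebra, independent of statsmodels
    k, n, z = 80, 100, 1.959963984540054
    p = k / n
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = (
        z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    )
    est = e.compute_proportion(k, n)
    assert est.ci_low == pytest.approx(center - half, abs=1e-12)
    assert est.ci_high == pytest.approx(center + half, abs=1e-12)


def test_odds_ratio_against_direct_arithmetic():
    est = e.compute_odds_ratio(WALKTHROUGH_TABLE)
    assert est.point == pytest.approx((939 * 247) / (232 * 801), rel=1e-12)
    assert est.point == pytest.approx(1.248, abs=5e-4)
    se = math.sqrt(1 / 939 + 1 / 232 + 1 / 801 + 1 / 247)
    assert est.se == pytest.approx(se, rel=1e-12)


def test_odds_ratio_symmetric_table_is_one():
    est = e.compute_odds_ratio(e.TwoByTwoCounts(50, 50, 50, 50))
    assert est.point == 1.0


def test_odds_ratio_continuity_correction():
    est = e.compute_odds_ratio(e.TwoByTwoCounts(10, 0, 5, 5))
    assert est.point == pytest.approx((10.5 * 5.5) / (0.5 * 5.5), rel=1e-12)
    assert math.isfinite(est.se)
    with pytest.raises(UndefinedMeasureError):
        e.compute_odds_ratio(e.TwoByTwoCounts(10, 0, 5, 5), continuity=False)


def test_odds_ratio_degenerate_table():
    with pytest.raises(UndefinedMeasureError):
        e.compute_odds_ratio(e.TwoByTwoCounts(0, 10, 0, 10))
    with pytest.raises(UndefinedMeasureError):
        e.compute_odds_ratio(e.TwoByTwoCounts(10, 0, 10, 0))


def test_odds_ratio_matches_statsmodels_table2x2():
    from statsmodels.stats.contingency_tables import Table2x2

    table = Table2x2(
        np.array([[939, 232], [801, 247]]), shift_zeros=False
    )
    est = e.compute_odds_ratio(WALKTHROUGH_TABLE)
    assert est.point == pytest.approx(table.oddsratio, rel=1e-12)
    lo, hi = table.oddsratio_confint()
    assert est.ci_low == pytest.approx(lo, rel=1e-9)
    assert est.ci_high == pytest.approx(hi, rel=1e-9)


def test_risk_ratio_against_direct_arithmetic():
    est = e.compute_risk_ratio(WALKTHROUGH_TABLE)
    assert est.point == pytest.approx((939 / 1171) / (801 / 1048), rel=1e-12)
    assert est.point == pytest.approx(1.0492, abs=1e-4)


def test_risk_ratio_identical_arms_is_one():
    est = e.compute_risk_ratio(e.TwoByTwoCounts(30, 70, 30, 70))
    assert est.point == 1.0


def test_risk_ratio_degenerate():
    with pytest.raises(UndefinedMeasureError):
        e.compute_risk_ratio(e.TwoByTwoCounts(0, 10, 0, 10))


@given(
    a=st.integers(1, 400),
    b=st.integers(1, 400),
    c=st.integers(1, 400),
    d=st.integers(1, 400),
)
@settings(max_examples=200, derandomize=True)
def test_arm_swap_reciprocity(a, b, c, d):
    counts = e.TwoByTwoCounts(a, b, c, d)
    forward = e.compute_odds_ratio(counts)
    backward = e.compute_odds_ratio(counts.swapped())
    assert forward.point * backward.point == pytest.approx(1.0, abs=1e-12)


@given(
    a=st.integers(1, 400),
    b=st.integers(1, 400),
    c=st.integers(1, 400),
    d=st.integers(1, 400),
)
@settings(max_examples=100, derandomize=True)
def test_log_scale_ci_multiplicatively_symmetric(a, b, c, d):
    est = e.compute_odds_ratio(e.TwoByTwoCounts(a, b, c, d))
    assert est.ci_low * est.ci_high == pytest.approx(est.point**2, rel=1e-9)


def test_walkthrough_statistic_recovers_reported_estimate(walkthrough):
    stat = walkthrough.evidence[0].statistic[0]
    est = e.statistic_to_estimate(stat)
    assert est.measure == "odds-ratio"
    assert est.point == 1.27
    assert (est.ci_low, est.ci_high) == (1.03, 1.58)
    assert est.ci_level == 0.95


def test_to_statistic_emits_interval_and_sample(walkthrough):
    counts = WALKTHROUGH_TABLE
    est = e.compute_proportion(939, 1171)
    stat = e.to_statistic(est)
    assert stat.number_of_events == 939
    assert stat.sample_size.total_participants == 1171
    interval = stat.attribute_estimate[0]
    assert interval.level == est.ci_level
    assert interval.range_low.value == est.ci_low

    stat_or = e.to_statistic(e.compute_odds_ratio(counts))
    codes = [c.code for c in stat_or.statistic_type.coding]
    assert codes == ["odds-ratio"]


def test_statistic_estimate_roundtrip_on_random_estimates():
    rng = np.random.default_rng(7)
    measures = ["odds-ratio", "risk-ratio", "risk-difference", "proportion"]
    for i in range(100):
        est = random_estimate(rng, measures[i % 4])
        back = e.statistic_to_estimate(e.to_statistic(est))
        assert back.measure == est.measure
        assert back.point == pytest.approx(est.point, rel=1e-12)
        assert back.se == pytest.approx(est.se, rel=1e-12)
        assert back.ci_low == pytest.approx(est.ci_low, rel=1e-12)
        assert back.ci_high == pytest.approx(est.ci_high, rel=1e-12)
        assert back.ci_level == pytest.approx(est.ci_level, rel=1e-12)


def test_se_recovered_from_ci_width():
    rng = np.random.default_rng(13)
    for _ in range(50):
        est = random_estimate(rng, "odds-ratio")
        stat = e.to_statistic(est)
        # strip the explicit standard-error attribute: force width recovery
        stat.attribute_estimate = [stat.attribute_estimate[0]]
        back = e.statistic_to_estimate(stat)
        assert back.se == pytest.approx(est.se, abs=1e-9)


def test_statistic_without_dispersion_is_rejected(walkthrough):
    stat = e.to_statistic(e.compute_odds_ratio(WALKTHROUGH_TABLE))
    stat.attribute_estimate = []
    with pytest.raises(EstimateError, match="interval"):
        e.statistic_to_estimate(stat)


def test_text_only_statistic_type_strict_vs_lenient(walkthrough):
    stat = e.to_statistic(e.compute_odds_ratio(WALKTHROUGH_TABLE))
    stat.statistic_type = e.CodeableConcept(text="odds ratio")
    with pytest.raises(EstimateError):
        e.statistic_to_estimate(stat, strict=True)
    est = e.statistic_to_estimate(stat, strict=False)
    assert est.measure == "odds-ratio"
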