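"""Potency ratios, G-test, interaction index, envelopes, and verdicts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from isobolar.dose_response import EDEstimate
from isobolar.isobole import (
    classify_combination,
    constancy_gtest,
    escalate_effect_level,
    g_statistic,
    interaction_index,
    isobole_envelope,
    max_common_effect,
    potency_ratio,
    PotencyRatio,
)
from isobolar.viability import CombinationObservation

from conftest import random_monotone_curve


def ed(point, level=50.0, agent="a", draws=None):
    return EDEstimate(
        agent=agent,
        effect_level=level,
        point=point,
        draws=None if draws is None else np.asarray(draws, float),
    )


# --- potency ratio -------------------------------------------------------


def test_equal_eds_give_unit_ratio():
    assert potency_ratio(ed(40.0), ed(40.0, agent="b")).ratio == 1.0


@given(
    a=st.floats(min_value=0.5, max_value=200.0),
    b=st.floats(min_value=0.5, max_value=200.0),
)
def test_swapping_agents_inverts_ratio(a, b):
    r = potency_ratio(ed(a), ed(b, agent="b")).ratio
    r_swapped = potency_ratio(ed(b, agent="b"), ed(a)).ratio
    assert r_swapped == pytest.approx(1.0 / r, rel=1e-12)


def test_mismatched_effect_levels_rejected():
    with pytest.raises(ValueError, match="same effect level"):
        potency_ratio(ed(40.0, level=50.0), ed(40.0, level=84.0, agent="b"))


def test_ratio_ci_from_paired_draws(rng):
    draws_a = rng.normal(51, 3, 1000)
    draws_b = rng.normal(44, 3, 1000)
    r = potency_ratio(ed(51.0, draws=draws_a), ed(44.0, agent="b", draws=draws_b))
    assert r.ci_lower < r.ratio < r.ci_upper
    lo, hi = np.quantile(draws_a / draws_b, [0.025, 0.975])
    assert r.ci_lower == pytest.approx(lo)
    assert r.ci_upper == pytest.approx(hi)


# --- max common effect ---------------------------------------------------


def test_max_common_effect_is_min_of_maxima(rng):
    for _ in range(20):
        ca, cb = random_monotone_curve(rng), random_monotone_curve(rng)
        expected = min(ca.mean_effect.max(), cb.mean_effect.max())
        assert max_common_effect(ca, cb) == expected


# --- G-test --------------------------------------------------------------


def test_g_statistic_worked_table():
    g, adjusted = g_statistic([[30, 10], [10, 30]])
    assert not adjusted
    assert g == pytest.approx(20.93, abs=5e-3)


def test_g_statistic_identical_proportions_is_zero():
    table = [[25, 75], [50, 150]]
    g, _ = g_statistic(table)
    assert g == pytest.approx(0.0, abs=1e-12)


def test_g_statistic_matches_scipy_log_likelihood(rng):
    for _ in range(50):
        table = rng.integers(1, 60, size=(2, 2))
        g, _ = g_statistic(table)
        g_ref = chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        ).statistic
        assert g == pytest.approx(g_ref, rel=1e-12)


def test_constancy_gtest_same_side_draws_flag_linear(rng):
    # both ratios concentrated above 1: proportions agree, p is large,
    # the linear-isobole reading stands
    r50 = PotencyRatio("a", "b", 50.0, 1.16, draws=rng.normal(1.16, 0.02, 2000))
    rmax = PotencyRatio("a", "b", 90.0, 1.07, draws=rng.normal(1.07, 0.01, 2000))
    res = constancy_gtest(r50, rmax)
    assert res.p_value > 0.05
    assert res.continuity_adjusted  # all draws > 1: a zero column


def test_constancy_gtest_detects_side_flip(rng):
    r50 = PotencyRatio("a", "b", 50.0, 1.4, draws=rng.normal(1.4, 0.05, 2000))
    rmax = PotencyRatio("a", "b", 90.0, 0.7, draws=rng.normal(0.7, 0.05, 2000))
    res = constancy_gtest(r50, rmax)
    assert res.p_value < 1e-6


def test_constancy_gtest_requires_draws():
    with pytest.raises(ValueError, match="draws"):
        constancy_gtest(
            PotencyRatio("a", "b", 50.0, 1.16),
            PotencyRatio("a", "b", 90.0, 1.07),
        )


# --- interaction index ---------------------------------------------------


def test_interaction_index_on_line_points():
    assert interaction_index(0.0, 44.0, 51.0, 44.0) == pytest.approx(1.0)
    assert interaction_index(25.5, 22.0, 51.0, 44.0) == pytest.approx(1.0)


def test_interaction_index_reported_combination():
    gamma = interaction_index(10.0, 20.0, 51.0, 44.0)
    assert gamma == pytest.approx(10 / 51 + 20 / 44, rel=1e-12)
    assert gamma < 1.0


# --- envelope ------------------------------------------------------------


def test_zero_variance_draws_collapse_envelope_to_line():
    d_a, d_b = np.full(500, 51.0), np.full(500, 44.0)
    env = isobole_envelope(ed(51.0, draws=d_a), ed(44.0, agent="b", draws=d_b))
    grid = np.linspace(0, 51, 7)
    lower, upper = env.band(grid)
    line = env.line_at(grid)
    assert np.allclose(lower, line) and np.allclose(upper, line)


def test_envelope_at_zero_dose_reduces_to_marginal_ci(rng):
    d_a = rng.normal(51, 5, 2000)
    d_b = rng.normal(44, 5, 2000)
    env = isobole_envelope(ed(51.0, draws=d_a), ed(44.0, agent="b", draws=d_b))
    lower, upper = env.band(0.0)
    lo, hi = np.quantile(d_b, [0.025, 0.975])
    assert lower == pytest.approx(lo) and upper == pytest.approx(hi)


def test_envelope_ordering_lower_line_upper(rng):
    for _ in range(20):
        d_a = np.abs(rng.normal(51, 8, 500)) + 1
        d_b = np.abs(rng.normal(44, 8, 500)) + 1
        env = isobole_envelope(
            ed(float(np.median(d_a)), draws=d_a),
            ed(float(np.median(d_b)), agent="b", draws=d_b),
        )
        grid = np.linspace(0, np.median(d_a), 11)
        lower, upper = env.band(grid)
        assert np.all(lower <= upper + 1e-12)


# --- classification ------------------------------------------------------


def classify(dose_a, dose_b, d_a, d_b):
    return classify_combination(
        ed(51.0, draws=d_a), ed(44.0, agent="b", draws=d_b), dose_a, dose_b
    )


def test_point_on_line_with_envelope_is_additive_consistent(rng):
    d_a = rng.normal(51, 4, 2000)
    d_b = rng.normal(44, 4, 2000)
    res = classify(25.5, 22.0, d_a, d_b)
    assert res.verdict == "additive-consistent"
    assert res.interaction_index == pytest.approx(1.0)


def test_point_below_line_within_wide_envelope_is_inconclusive(rng):
    # wide intercept uncertainty swallows the sub-additive point
    d_a = np.abs(rng.normal(51, 25, 2000)) + 1
    d_b = np.abs(rng.normal(44, 25, 2000)) + 1
    res = classify(10.0, 20.0, d_a, d_b)
    assert res.interaction_index < 1
    assert res.verdict == "inconclusive"


def test_point_below_tight_envelope_is_synergistic(rng):
    d_a = rng.normal(51, 1, 2000)
    d_b = rng.normal(44, 1, 2000)
    res = classify(10.0, 20.0, d_a, d_b)
    assert res.verdict == "synergistic"
    assert res.dose_b < res.envelope_lower


def test_point_above_tight_envelope_is_antagonistic(rng):
    d_a = rng.normal(51, 1, 2000)
    d_b = rng.normal(44, 1, 2000)
    res = classify(40.0, 40.0, d_a, d_b)
    assert res.verdict == "antagonistic-consistent"


def test_agent_swap_preserves_gamma_and_verdict(rng):
    d_a = rng.normal(51, 3, 2000)
    d_b = rng.normal(44, 3, 2000)
    fwd = classify_combination(
        ed(51.0, draws=d_a), ed(44.0, agent="b", draws=d_b), 10.0, 20.0
    )
    rev = classify_combination(
        ed(44.0, agent="b", draws=d_b), ed(51.0, draws=d_a), 20.0, 10.0
    )
    assert fwd.interaction_index == pytest.approx(rev.interaction_index, rel=1e-12)
    assert fwd.verdict == rev.verdict


# --- escalation ----------------------------------------------------------


def combo(effects):
    return CombinationObservation(
        agent_a="a", agent_b="b", dose_a=10.0, dose_b=20.0, effects=np.asarray(effects, float)
    )


def test_replicates_all_at_fifty_stay_at_fifty():
    dec = escalate_effect_level(combo([50.0, 50.0, 50.0]))
    assert dec.t_stat == 0.0
    assert dec.level == 50.0


def test_consistently_high_effect_escalates_to_floor_of_mean():
    dec = escalate_effect_level(combo([76.8, 84.6, 92.4]))
    assert dec.mean_effect == pytest.approx(84.6)
    assert dec.p_value < 0.05
    assert dec.level == 84.0


def test_high_but_noisy_effect_stays_at_fifty():
    dec = escalate_effect_level(combo([20.0, 60.0, 100.0]))
    assert dec.p_value >= 0.05
    assert dec.level == 50.0


def test_escalation_needs_replication():
    with pytest.raises(ValueError):
        CombinationObservation(
            agent_a="a", agent_b="b", dose_a=1.0, dose_b=1.0, effects=[80.0]
        )
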