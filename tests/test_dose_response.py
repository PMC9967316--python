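"""Interpolation exactness, first-crossing rules, and bootstrap behavior."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from isobolar.dose_response import (
    EffectLevelUnreachable,
    UnreliableBootstrap,
    bootstrap_ed,
    bootstrap_ed_multi,
    fit_linear,
    interpolate_ed,
)
from isobolar.viability import EffectCurve

from conftest import make_linear_curve, random_monotone_curve


def curve_from_means(doses, means, agent="a"):
    return EffectCurve(
        agent=agent,
        doses=np.asarray(doses, float),
        effects=[np.array([m, m]) for m in means],
    )


# --- linear screen -------------------------------------------------------


def test_fit_linear_exact_line():
    curve = curve_from_means([10, 20, 30, 40], [20, 40, 60, 80])
    res = fit_linear(curve)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0)
    assert res.p_value < 0.001


def test_fit_linear_constant_effect():
    res = fit_linear(curve_from_means([10, 20, 30], [15, 15, 15]))
    assert res.slope == pytest.approx(0.0)
    assert res.f_stat == 0.0
    assert res.p_value == 1.0


def test_fit_linear_identical_doses_error():
    curve = EffectCurve(
        agent="a", doses=[10.0], effects=[np.array([1.0, 2.0, 3.0])]
    )
    with pytest.raises(ValueError):
        fit_linear(curve)


def test_fit_linear_nonsignificant_warns(caplog):
    rng = np.random.default_rng(4)
    curve = curve_from_means([10, 20, 30, 40, 50], rng.normal(30, 5, 5))
    with caplog.at_level("WARNING"):
        fit_linear(curve)
    # flat noisy data: either warned or (rarely) significant by chance
    assert any("not significant" in r.message for r in caplog.records)


# --- interpolation -------------------------------------------------------


def test_interpolant_reproduces_nodes_exactly():
    curve = curve_from_means([50, 100, 150], [50, 100, 150])
    assert interpolate_ed(curve, 50.0).point == 50.0
    assert interpolate_ed(curve, 100.0).point == 100.0


def test_linear_truth_on_extended_gradient_gives_ed50_of_51():
    # effect = 0.98 * dose on the naloxone-style grid: the interpolant
    # reproduces the line, so ED50 = 50/0.98 = 51.02
    doses = [0.1, 1, 10, 20, 40, 70, 110]
    curve = curve_from_means(doses, [0.98 * d for d in doses])
    est = interpolate_ed(curve, 50.0)
    assert est.point == pytest.approx(50.0 / 0.98, abs=1e-9)
    assert round(est.point) == 51


def test_effect_level_above_maximum_is_refused():
    curve = curve_from_means([10, 20, 40], [10, 20, 39.2])
    with pytest.raises(EffectLevelUnreachable, match="extrapolate"):
        interpolate_ed(curve, 50.0)


def test_first_crossing_on_non_monotone_means():
    # means rise above 50, dip, and rise again: the smallest crossing wins
    curve = curve_from_means([10, 20, 30, 40], [20, 55, 45, 80])
    est = interpolate_ed(curve, 50.0)
    # oracle: brute-force scan of the same interpolant on a fine grid
    x = np.array([0.0, 10, 20, 30, 40])
    y = np.array([0.0, 20, 55, 45, 80])
    f = PchipInterpolator(x, y)
    grid = np.linspace(0, 40, 400001)
    first = grid[np.argmax(f(grid) >= 50.0)]
    assert est.point == pytest.approx(first, abs=1e-3)
    assert est.point < 20.0


def test_ed_monotone_in_effect_level(rng):
    for _ in range(50):
        curve = random_monotone_curve(rng)
        top = curve.max_mean_effect
        levels = np.sort(rng.uniform(0.5, top, size=4))
        eds = [interpolate_ed(curve, e).point for e in levels]
        assert all(a <= b + 1e-9 for a, b in zip(eds, eds[1:]))


def test_interpolant_has_no_overshoot(rng):
    # shape preservation: between consecutive nodes the interpolant stays
    # within the node values, so no spurious ED roots can appear
    for _ in range(25):
        curve = random_monotone_curve(rng)
        x = np.concatenate(([0.0], curve.doses))
        y = np.concatenate(([0.0], curve.mean_effect))
        f = PchipInterpolator(x, y)
        for lo, hi, ylo, yhi in zip(x[:-1], x[1:], y[:-1], y[1:]):
            seg = f(np.linspace(lo, hi, 200))
            assert seg.min() >= min(ylo, yhi) - 1e-9
            assert seg.max() <= max(ylo, yhi) + 1e-9


def test_interpolation_needs_three_points():
    curve = EffectCurve(
        agent="a", doses=[10.0], effects=[np.array([30.0, 31.0])]
    )
    with pytest.raises(ValueError, match="3"):
        interpolate_ed(curve, 20.0)


# --- bootstrap -----------------------------------------------------------


def test_zero_noise_bootstrap_ci_width_zero():
    curve = make_linear_curve(1.0, [10, 20, 40, 60], noise_sd=0.0)
    est = bootstrap_ed(curve, 30.0, n_boot=500, seed=1)
    assert est.ci_lower == est.ci_upper == est.point == pytest.approx(30.0)


def test_bootstrap_deterministic_given_seed(rng):
    curve = make_linear_curve(1.0, [10, 20, 40, 60], noise_sd=5.0, rng=rng)
    a = bootstrap_ed(curve, 30.0, n_boot=500, seed=7)
    b = bootstrap_ed(curve, 30.0, n_boot=500, seed=7)
    assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
    assert np.array_equal(a.draws, b.draws)
    c = bootstrap_ed(curve, 30.0, n_boot=500, seed=8)
    assert (a.ci_lower, a.ci_upper) != (c.ci_lower, c.ci_upper)


def test_bootstrap_rejects_tiny_replication():
    curve = make_linear_curve(1.0, [10, 20, 40], noise_sd=1.0)
    with pytest.raises(ValueError, match="200"):
        bootstrap_ed(curve, 20.0, n_boot=50, seed=1)


def test_multi_level_shares_resamples_and_orders_levels(rng):
    curve = make_linear_curve(1.0, [10, 20, 40, 60, 80], noise_sd=4.0, rng=rng)
    eds = bootstrap_ed_multi(curve, [30.0, 60.0], n_boot=500, seed=3)
    assert set(eds) == {30.0, 60.0}
    # paired draws: each resampled monotone curve gives ED30 <= ED60
    both = np.isfinite(eds[30.0].draws) & np.isfinite(eds[60.0].draws)
    assert np.all(eds[30.0].draws[both] <= eds[60.0].draws[both] + 1e-9)


@pytest.mark.parametrize(
    "n_replicates, lo, hi",
    [
        (6, 0.78, 0.92),  # known small-n undercoverage of percentile CIs
        (30, 0.90, 0.985),  # converges to ~nominal with replication
    ],
)
def test_bootstrap_coverage_by_replication(n_replicates, lo, hi):
    # empirical 95% CI coverage for a known ED50 = 40 linear truth
    rng = np.random.default_rng(808)
    doses = np.array([10.0, 25.0, 40.0, 55.0, 70.0])
    covered = 0
    runs = 300
    for _ in range(runs):
        effects = [1.25 * d + rng.normal(0, 5.0, n_replicates) for d in doses]
        curve = EffectCurve(agent="a", doses=doses, effects=effects)
        est = bootstrap_ed(curve, 50.0, n_boot=1000, seed=int(rng.integers(2**31)))
        covered += est.ci_lower <= 40.0 <= est.ci_upper
    assert lo <= covered / runs <= hi


def test_boundary_level_unreliable_strict_raises_nonstrict_omits():
    # a level exactly at the observed maximum mean effect sits on the
    # boundary of the bootstrap distribution: with n = 3 skewed replicates
    # at the top dose, over half the resampled curves fall short of it
    from isobolar.synthetic_data import loewe_additive_truth, simulate_plate
    from isobolar.viability import build_effect_curve, normalize

    viab = normalize(simulate_plate(loewe_additive_truth(seed=0)))
    curve = build_effect_curve(viab, "naloxone")
    top = curve.max_mean_effect
    with pytest.raises(UnreliableBootstrap, match="could not reach"):
        bootstrap_ed_multi(curve, [50.0, top], n_boot=2000, seed=5000)
    eds = bootstrap_ed_multi(
        curve, [50.0, top], n_boot=2000, seed=5000, strict=False
    )
    assert 50.0 in eds and top not in eds
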