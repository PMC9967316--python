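"""Dose-effect fitting and effective-dose interpolation with bootstrap CIs.

The effective dose ED_E is the smallest dose at which a shape-preserving
piecewise cubic interpolant (PCHIP) through the per-dose mean effects,
anchored at (0, 0), first reaches the effect level E.  PCHIP introduces no
values outside the range of neighbouring nodes, so on monotone data no
spurious crossings can arise; on non-monotone data the first-crossing rule
returns the smallest effective dose.  Extrapolation beyond the largest
tested dose is refused.

Uncertainty comes from a nonparametric bootstrap that resamples replicate
wells within each dose, rebuilds the interpolant, and re-solves for ED_E;
confidence intervals are percentile intervals over the resampled doses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .viability import EffectCurve

logger = logging.getLogger(__name__)

_BISECT_ITERS = 80  # dose bracket halved per iteration: ~1e-24 relative


class EffectLevelUnreachable(ValueError):
    """The requested effect level exceeds the maximum observed mean effect
    (would require extrapolation beyond the tested dose range)."""


class UnreliableBootstrap(RuntimeError):
    """Too many bootstrap resamples could not reach the effect level."""


@dataclass
class LinearFitResult:
    """Ordinary least squares of mean effect on dose with slope F-test.

    Used as a significance screen before interpolation, never as the
    dose-effect model itself.
    """

    agent: str
    slope: float
    intercept: float
    f_stat: float
    p_value: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.f_stat < 0:
            raise ValueError(f"negative F statistic: {self.f_stat}")


@dataclass
class EDEstimate:
    """Interpolated dose producing effect level E, with optional bootstrap CI.

    ``draws`` holds the full-length vector of bootstrap ED draws (NaN where
    the level was unreachable in a resample) so that downstream consumers
    can pair draws by resample index across agents and effect levels.
    """

    agent: str
    effect_level: float
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95
    n_boot: int = 0
    n_unreachable: int = 0
    method: str = "pchip-first-crossing"
    draws: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.point <= 0:
            raise ValueError(f"ED point estimate must be > 0, got {self.point}")
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and not (self.ci_lower <= self.point <= self.ci_upper)
        ):
            # percentile CIs can rarely exclude the point estimate; keep
            # the interval but record the anomaly
            logger.warning(
                "agent %s E=%g: point %.4g outside percentile CI "
                "[%.4g, %.4g]",
                self.agent,
                self.effect_level,
                self.point,
                self.ci_lower,
                self.ci_upper,
            )


def fit_linear(curve: EffectCurve) -> LinearFitResult:
    """OLS of per-dose mean effect on dose, with the slope F-test.

    A non-significant fit (p >= 0.05) logs a warning: interpolation can
    still proceed, but the dose-effect trend is weak.
    """
    x = curve.doses
    y = curve.mean_effect
    if len(x) < 3:
        raise ValueError("linear screen needs >= 3 dose points")
    if np.ptp(x) == 0:
        raise ValueError("all doses identical; cannot fit dose-effect line")
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        f_stat, p_value, r_squared = 0.0, 1.0, 0.0
    else:
        with np.errstate(divide="ignore"):  # exact fits have zero stderr
            t = res.slope / res.stderr if res.stderr > 0 else np.inf
        f_stat = float(t * t)
        p_value = float(res.pvalue)
        r_squared = float(res.rvalue**2)
    if p_value >= 0.05:
        logger.warning(
            "agent %s: dose-effect linear screen not significant "
            "(p = %.3g)",
            curve.agent,
            p_value,
        )
    return LinearFitResult(
        agent=curve.agent,
        slope=float(res.slope),
        intercept=float(res.intercept),
        f_stat=f_stat,
        p_value=p_value,
        r_squared=r_squared,
        n=len(x),
    )


def _anchored_nodes(curve: EffectCurve) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Node doses/effects with the (0, 0) anchor prepended; any observed
    dose-0 point is replaced by the exact anchor."""
    nz = curve.nonzero()
    if len(nz.doses) < 3:
        raise ValueError(
            "interpolation needs >= 3 distinct nonzero doses, got "
            f"{len(nz.doses)}"
        )
    x = np.concatenate(([0.0], nz.doses))
    y = np.concatenate(([0.0], nz.mean_effect))
    return x, y, nz.effects


def _first_crossing_batch(
    x: np.ndarray, ynodes: np.ndarray, level: float
) -> np.ndarray:
    """Smallest dose where the PCHIP through (x, column of ynodes) reaches
    ``level``; NaN where the level is never reached.

    ``ynodes`` has shape (m, B): one interpolant per column, solved for all
    columns at once by bisection on the piecewise-cubic coefficients.
    """
    m, B = ynodes.shape
    out = np.full(B, np.nan)
    diff = ynodes - level
    bracket = diff[:-1] * diff[1:] <= 0.0
    has = bracket.any(axis=0)
    if not has.any():
        return out
    cols = np.flatnonzero(has)
    iv = np.argmax(bracket[:, cols], axis=0)  # first bracketing interval
    ylo = ynodes[iv, cols]
    yhi = ynodes[iv + 1, cols]

    # exact node hits stay exact
    hit_lo = ylo == level
    hit_hi = (~hit_lo) & (yhi == level)
    out[cols[hit_lo]] = x[iv[hit_lo]]
    out[cols[hit_hi]] = x[iv[hit_hi] + 1]

    solve = ~(hit_lo | hit_hi)
    if not solve.any():
        return out
    scols = cols[solve]
    siv = iv[solve]
    interp = PchipInterpolator(x, ynodes, axis=0, extrapolate=False)
    c = interp.c  # (4, m-1, B)
    c0 = c[0, siv, scols]
    c1 = c[1, siv, scols]
    c2 = c[2, siv, scols]
    c3 = c[3, siv, scols]
    h = x[siv + 1] - x[siv]
    lo = np.zeros_like(h)
    hi = h.copy()
    f_lo_sign = np.sign(ynodes[siv, scols] - level)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        fm = ((c0 * mid + c1) * mid + c2) * mid + c3 - level
        same = np.sign(fm) == f_lo_sign
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    out[scols] = x[siv] + 0.5 * (lo + hi)
    return out


def interpolate_ed(curve: EffectCurve, effect_level: float) -> EDEstimate:
    """Point estimate of ED_E by first crossing of the anchored PCHIP.

    Exact on nodes: requesting the mean effect observed at a tested dose
    returns that dose.  Raises :class:`EffectLevelUnreachable` when E
    exceeds the maximum observed mean effect (no extrapolation).
    """
    x, y, _ = _anchored_nodes(curve)
    if not (0.0 < effect_level):
        raise ValueError(f"effect level must be > 0, got {effect_level}")
    if effect_level > y.max():
        raise EffectLevelUnreachable(
            f"agent {curve.agent!r}: effect level {effect_level:g}% exceeds "
            f"maximum observed mean effect {y.max():.4g}% "
            "(refusing to extrapolate)"
        )
    ed = _first_crossing_batch(x, y[:, None], effect_level)[0]
    if math.isnan(ed):  # pragma: no cover - guarded by the max check
        raise EffectLevelUnreachable(
            f"agent {curve.agent!r}: no crossing found for E={effect_level:g}"
        )
    return EDEstimate(agent=curve.agent, effect_level=float(effect_level), point=float(ed))


def _resampled_mean_matrix(
    effects: Sequence[np.ndarray], n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_boot, n_dose) matrix of within-dose resampled replicate means."""
    cols = []
    for e in effects:
        n = len(e)
        idx = rng.integers(0, n, size=(n_boot, n))
        cols.append(e[idx].mean(axis=1))
    return np.column_stack(cols)


def bootstrap_ed(
    curve: EffectCurve,
    effect_level: float,
    n_boot: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> EDEstimate:
    """ED_E with a percentile bootstrap CI over within-dose replicate
    resampling.  See :func:`bootstrap_ed_multi` for several levels sharing
    one set of resamples."""
    return bootstrap_ed_multi(
        curve, [effect_level], n_boot=n_boot, seed=seed, ci_level=ci_level
    )[effect_level]


def bootstrap_ed_multi(
    curve: EffectCurve,
    effect_levels: Sequence[float],
    n_boot: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
    strict: bool = True,
) -> dict[float, EDEstimate]:
    """Bootstrap ED estimates at several effect levels from one common set
    of resampled curves, so draws are paired across levels by resample
    index (needed for potency-ratio constancy testing).

    Resamples where a level is unreachable are dropped from that level's
    CI and counted; if more than half of the resamples are unreachable the
    CI is declared unreliable and :class:`UnreliableBootstrap` is raised
    (``strict=False`` instead omits that level from the result with a
    warning, for levels that sit on the boundary of the observed range).
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    if not (0.0 < ci_level < 1.0):
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    x, _, effects = _anchored_nodes(curve)
    if any(len(e) < 1 for e in effects):
        raise ValueError("replicate-level effects required at every dose")
    rng = np.random.default_rng(seed)
    means = _resampled_mean_matrix(effects, n_boot, rng)  # (B, m-1)
    ynodes = np.vstack([np.zeros(n_boot), means.T])  # (m, B)
    alpha = 1.0 - ci_level
    out: dict[float, EDEstimate] = {}
    for level in effect_levels:
        point_est = interpolate_ed(curve, level)
        draws = _first_crossing_batch(x, ynodes, level)
        finite = draws[np.isfinite(draws)]
        n_bad = n_boot - len(finite)
        if n_bad > 0.5 * n_boot:
            msg = (
                f"agent {curve.agent!r} E={level:g}: {n_bad}/{n_boot} "
                "bootstrap resamples could not reach the effect level; "
                "CI unreliable (level too close to the observed maximum)"
            )
            if strict:
                raise UnreliableBootstrap(msg)
            logger.warning("%s; level omitted", msg)
            continue
        if n_bad:
            logger.info(
                "agent %s E=%g: dropped %d/%d unreachable resamples",
                curve.agent,
                level,
                n_bad,
                n_boot,
            )
        lo, hi = np.quantile(finite, [alpha / 2, 1 - alpha / 2])
        out[level] = EDEstimate(
            agent=curve.agent,
            effect_level=float(level),
            point=point_est.point,
            ci_lower=float(lo),
            ci_upper=float(hi),
            ci_level=ci_level,
            n_boot=n_boot,
            n_unreachable=int(n_bad),
            draws=draws,
        )
    return out
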