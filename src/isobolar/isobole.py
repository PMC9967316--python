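"""Loewe-additivity isobolographic synergy analysis.

At a fixed effect level E the additivity isobole is the line joining the
single-agent effective doses (ED_E^A, 0) and (0, ED_E^B); a combination
(a, b) producing effect E while lying below that line is supra-additive
(synergistic in the Loewe sense).  The linearity of the isobole is
justified when the potency ratio R_E = ED_E^A / ED_E^B does not vary with
E (Tallarida's condition), which is screened here with a G-test on
dichotomised bootstrap draws of R at 50% and at the maximum common effect.
Confidence envelopes around the isobole come from paired bootstrap draws
of the two axis intercepts; a combination is called synergistic only when
it falls strictly below the lower envelope.

When the observed combination effect is consistently above 50% (one-sample
t-test), the analysis level is escalated to the floor of the observed mean
effect, so the combination point is judged against the isobole of the
effect it actually produces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dose_response import EDEstimate
from .viability import CombinationObservation, EffectCurve

logger = logging.getLogger(__name__)

VERDICTS = (
    "synergistic",
    "additive-consistent",
    "antagonistic-consistent",
    "inconclusive",
)


@dataclass
class PotencyRatio:
    """R_E = ED_E(agent A) / ED_E(agent B), dimensionless, with optional
    percentile CI from index-paired bootstrap draws."""

    agent_a: str
    agent_b: str
    effect_level: float
    ratio: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95
    draws: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"potency ratio must be > 0, got {self.ratio}")


@dataclass
class GTestResult:
    """Likelihood-ratio (G) test of a 2x2 contingency table, 1 df."""

    g_stat: float
    p_value: float
    table: np.ndarray
    continuity_adjusted: bool = False
    df: int = 1


@dataclass
class IsoboleEnvelope:
    """Additivity line at one effect level with pointwise bootstrap
    confidence envelopes.

    ``draws_a``/``draws_b`` are index-paired bootstrap draws of the two
    axis intercepts (NaN where a draw was unreachable); envelopes at an
    agent-A dose ``a`` are the pointwise quantiles of the B-axis value
    ed_b * (1 - a / ed_a) over the valid paired draws.
    """

    effect_level: float
    ed_a: float
    ed_b: float
    ci_level: float
    draws_a: np.ndarray = field(repr=False)
    draws_b: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.draws_a = np.asarray(self.draws_a, dtype=float)
        self.draws_b = np.asarray(self.draws_b, dtype=float)
        if self.draws_a.shape != self.draws_b.shape:
            raise ValueError("paired draws must have equal length")
        self._valid = np.isfinite(self.draws_a) & np.isfinite(self.draws_b)
        if not self._valid.any():
            raise ValueError("no valid paired draws for the envelope")

    def line_at(self, a: np.ndarray | float) -> np.ndarray | float:
        """B-axis value of the additivity line at agent-A dose ``a``."""
        return self.ed_b * (1.0 - np.asarray(a, dtype=float) / self.ed_a)

    def band(self, a: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise (lower, upper) envelope quantiles at dose(s) ``a``."""
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        da = self.draws_a[self._valid][:, None]
        db = self.draws_b[self._valid][:, None]
        vals = db * (1.0 - a_arr[None, :] / da)
        alpha = 1.0 - self.ci_level
        lower = np.quantile(vals, alpha / 2, axis=0)
        upper = np.quantile(vals, 1 - alpha / 2, axis=0)
        if np.isscalar(a) or np.ndim(a) == 0:
            return float(lower[0]), float(upper[0])
        return lower, upper


@dataclass
class EscalationDecision:
    """Whether (and to what) the analysis effect level is escalated."""

    mean_effect: float
    se: float
    t_stat: float
    p_value: float
    level: float
    alpha: float = 0.05


@dataclass
class IsoboleAssessment:
    """Verdict for one combination dose pair at one effect level."""

    effect_level: float
    agent_a: str
    agent_b: str
    ed_a: EDEstimate
    ed_b: EDEstimate
    dose_a: float
    dose_b: float
    interaction_index: float
    envelope_lower: float
    envelope_upper: float
    line_value: float
    verdict: str
    ci_level: float
    gtest: GTestResult | None = None
    envelope: IsoboleEnvelope | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def potency_ratio(ed_a: EDEstimate, ed_b: EDEstimate, ci_level: float = 0.95) -> PotencyRatio:
    """R_E = ED_E^A / ED_E^B; CI from index-paired bootstrap draws when
    both estimates carry draws of equal length."""
    if ed_a.effect_level != ed_b.effect_level:
        raise ValueError(
            "potency ratio requires estimates at the same effect level, got "
            f"{ed_a.effect_level} and {ed_b.effect_level}"
        )
    ratio = ed_a.point / ed_b.point
    ci_lower = ci_upper = None
    draws = None
    if (
        ed_a.draws is not None
        and ed_b.draws is not None
        and len(ed_a.draws) == len(ed_b.draws)
    ):
        draws = ed_a.draws / ed_b.draws
        finite = draws[np.isfinite(draws)]
        if len(finite):
            alpha = 1.0 - ci_level
            lo, hi = np.quantile(finite, [alpha / 2, 1 - alpha / 2])
            ci_lower, ci_upper = float(lo), float(hi)
    return PotencyRatio(
        agent_a=ed_a.agent,
        agent_b=ed_b.agent,
        effect_level=float(ed_a.effect_level),
        ratio=float(ratio),
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        ci_level=ci_level,
        draws=draws,
    )


def max_common_effect(curve_a: EffectCurve, curve_b: EffectCurve) -> float:
    """Largest effect level at which both agents' EDs exist without
    extrapolation: the smaller of the two curves' maximum mean effects."""
    return float(min(curve_a.max_mean_effect, curve_b.max_mean_effect))


def g_statistic(table: np.ndarray) -> tuple[float, bool]:
    """Likelihood-ratio statistic G = 2 * sum O * ln(O / E) of a
    contingency table (expected counts from the independence model).

    Returns (G, continuity_adjusted): when any expected count is zero the
    whole table gets a +0.5 adjustment before computing G.
    """
    obs = np.asarray(table, dtype=float)
    adjusted = False
    expected = _expected_counts(obs)
    if np.any(expected == 0):
        logger.info("zero expected cell count; applying +0.5 adjustment")
        obs = obs + 0.5
        expected = _expected_counts(obs)
        adjusted = True
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    return max(g, 0.0), adjusted


def _expected_counts(obs: np.ndarray) -> np.ndarray:
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    return rows @ cols / total


def constancy_gtest(ratio_50: PotencyRatio, ratio_max: PotencyRatio) -> GTestResult:
    """G-test of whether the potency ratio is consistently on the same side
    of 1 at the two effect levels.

    Each ratio's bootstrap draws are dichotomised as > 1 versus <= 1; the
    resulting 2x2 table (effect level x category) is tested with
    G = 2 * sum O ln(O / E) against chi-squared with 1 df.  A
    non-significant p justifies treating the additivity isobole as linear
    (dose-independent relative potency).
    """
    rows = []
    for r in (ratio_50, ratio_max):
        if r.draws is None:
            raise ValueError(
                "constancy G-test needs bootstrap draws on both ratios"
            )
        d = r.draws[np.isfinite(r.draws)]
        if len(d) == 0:
            raise ValueError("a potency ratio has no valid bootstrap draws")
        gt = int((d > 1.0).sum())
        rows.append([gt, len(d) - gt])
    table = np.array(rows, dtype=float)
    g, adjusted = g_statistic(table)
    p = float(stats.chi2.sf(g, df=1))
    return GTestResult(g_stat=g, p_value=p, table=table, continuity_adjusted=adjusted)


def interaction_index(a: float, b: float, ed_a: float, ed_b: float) -> float:
    """Linear-isobole interaction index gamma = a/ED_A + b/ED_B.

    gamma < 1 places the combination below the additivity line
    (supra-additive), gamma = 1 on it, gamma > 1 above it.
    """
    if ed_a <= 0 or ed_b <= 0:
        raise ValueError("effective doses must be positive")
    if a < 0 or b < 0:
        raise ValueError("combination doses must be non-negative")
    return a / ed_a + b / ed_b


def isobole_envelope(
    ed_a: EDEstimate, ed_b: EDEstimate, ci_level: float = 0.95
) -> IsoboleEnvelope:
    """Pointwise confidence envelope of the additivity line from paired
    bootstrap draws of the two axis intercepts."""
    if ed_a.effect_level != ed_b.effect_level:
        raise ValueError("envelope requires estimates at the same effect level")
    if ed_a.draws is None or ed_b.draws is None:
        raise ValueError("envelope requires bootstrap draws on both estimates")
    if len(ed_a.draws) != len(ed_b.draws):
        raise ValueError("paired draws must have equal length")
    return IsoboleEnvelope(
        effect_level=float(ed_a.effect_level),
        ed_a=ed_a.point,
        ed_b=ed_b.point,
        ci_level=ci_level,
        draws_a=ed_a.draws,
        draws_b=ed_b.draws,
    )


def classify_combination(
    ed_a: EDEstimate,
    ed_b: EDEstimate,
    dose_a: float,
    dose_b: float,
    ci_level: float = 0.95,
    gtest: GTestResult | None = None,
) -> IsoboleAssessment:
    """Verdict for a combination (dose_a, dose_b) at the estimates' effect
    level.

    synergistic: strictly below the lower envelope; antagonistic-consistent:
    strictly above the upper envelope; otherwise additive-consistent when
    the interaction index gamma >= 1, and inconclusive when gamma < 1 (the
    point sits below the line but inside its confidence band).  Ties with
    an envelope bound count as within the band.
    """
    env = isobole_envelope(ed_a, ed_b, ci_level=ci_level)
    gamma = interaction_index(dose_a, dose_b, ed_a.point, ed_b.point)
    lower, upper = env.band(dose_a)
    if dose_b < lower:
        verdict = "synergistic"
    elif dose_b > upper:
        verdict = "antagonistic-consistent"
    elif gamma < 1.0:
        verdict = "inconclusive"
    else:
        verdict = "additive-consistent"
    return IsoboleAssessment(
        effect_level=env.effect_level,
        agent_a=ed_a.agent,
        agent_b=ed_b.agent,
        ed_a=ed_a,
        ed_b=ed_b,
        dose_a=float(dose_a),
        dose_b=float(dose_b),
        interaction_index=float(gamma),
        envelope_lower=float(lower),
        envelope_upper=float(upper),
        line_value=float(env.line_at(dose_a)),
        verdict=verdict,
        ci_level=ci_level,
        gtest=gtest,
        envelope=env,
    )


def escalate_effect_level(
    combo: CombinationObservation, alpha: float = 0.05
) -> EscalationDecision:
    """Choose the analysis effect level from the observed combination
    effect.

    One-sample t-test of the replicate effects against 50%: when the mean
    is consistently above 50 (p < alpha and mean > 50) the level escalates
    to floor(mean effect); otherwise it stays at 50.
    """
    if combo.n < 2:
        raise ValueError("escalation test needs >= 2 replicates")
    t_stat, p_value = stats.ttest_1samp(combo.effects, 50.0)
    t_stat, p_value = float(t_stat), float(p_value)
    if math.isnan(t_stat):  # zero variance replicates all equal to 50
        t_stat, p_value = 0.0, 1.0
    if p_value < alpha and combo.mean_effect > 50.0:
        level = float(math.floor(combo.mean_effect))
    else:
        level = 50.0
    return EscalationDecision(
        mean_effect=combo.mean_effect,
        se=combo.se,
        t_stat=t_stat,
        p_value=p_value,
        level=level,
        alpha=alpha,
    )
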