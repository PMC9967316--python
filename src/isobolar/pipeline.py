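"""End-to-end synergy analysis driver.

Chains the stages: absorbance normalisation -> per-agent effect curves ->
linear significance screen -> ED bootstrap at the 50%, maximum-common, and
(possibly) escalated effect levels from one shared set of resamples ->
potency ratios and their constancy G-test -> isobole verdicts at 50% and
at the escalated level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

from .assay_io import WellRecord
from .dose_response import (
    EDEstimate,
    LinearFitResult,
    UnreliableBootstrap,
    bootstrap_ed_multi,
    fit_linear,
)
from .isobole import (
    EscalationDecision,
    GTestResult,
    IsoboleAssessment,
    PotencyRatio,
    classify_combination,
    constancy_gtest,
    escalate_effect_level,
    max_common_effect,
    potency_ratio,
)
from .viability import (
    CombinationObservation,
    EffectCurve,
    build_effect_curve,
    combination_observation,
    normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class SynergyAnalysis:
    """Every product of one two-agent synergy analysis."""

    agent_a: str
    agent_b: str
    curve_a: EffectCurve
    curve_b: EffectCurve
    fit_a: LinearFitResult
    fit_b: LinearFitResult
    combination: CombinationObservation
    ed50_a: EDEstimate
    ed50_b: EDEstimate
    ratio_50: PotencyRatio
    ratio_max: PotencyRatio | None
    max_effect_level: float
    gtest: GTestResult | None
    isobole_linear: bool | None
    escalation: EscalationDecision
    assessment_50: IsoboleAssessment
    assessment_escalated: IsoboleAssessment

    @property
    def final_verdict(self) -> str:
        return self.assessment_escalated.verdict

    def to_dict(self) -> dict[str, Any]:
        """JSON-ready summary (consumed by ``assay_io.write_report``)."""

        def ed(e: EDEstimate) -> dict[str, Any]:
            return {
                "agent": e.agent,
                "effect_level": e.effect_level,
                "point": e.point,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "ci_level": e.ci_level,
                "n_boot": e.n_boot,
                "n_unreachable": e.n_unreachable,
                "method": e.method,
            }

        def ratio(r: PotencyRatio) -> dict[str, Any]:
            return {
                "effect_level": r.effect_level,
                "ratio": r.ratio,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
            }

        def assessment(a: IsoboleAssessment) -> dict[str, Any]:
            return {
                "effect_level": a.effect_level,
                "ed_a": ed(a.ed_a),
                "ed_b": ed(a.ed_b),
                "dose_a": a.dose_a,
                "dose_b": a.dose_b,
                "interaction_index": a.interaction_index,
                "envelope_lower": a.envelope_lower,
                "envelope_upper": a.envelope_upper,
                "line_value": a.line_value,
                "verdict": a.verdict,
                "ci_level": a.ci_level,
            }

        return {
            "agents": [self.agent_a, self.agent_b],
            "linear_fits": {
                self.agent_a: {
                    "slope": self.fit_a.slope,
                    "intercept": self.fit_a.intercept,
                    "f_stat": self.fit_a.f_stat,
                    "p_value": self.fit_a.p_value,
                    "r_squared": self.fit_a.r_squared,
                    "n": self.fit_a.n,
                },
                self.agent_b: {
                    "slope": self.fit_b.slope,
                    "intercept": self.fit_b.intercept,
                    "f_stat": self.fit_b.f_stat,
                    "p_value": self.fit_b.p_value,
                    "r_squared": self.fit_b.r_squared,
                    "n": self.fit_b.n,
                },
            },
            "combination": {
                "dose_a": self.combination.dose_a,
                "dose_b": self.combination.dose_b,
                "mean_effect": self.combination.mean_effect,
                "se": self.combination.se,
                "n": self.combination.n,
            },
            "ed50": {self.agent_a: ed(self.ed50_a), self.agent_b: ed(self.ed50_b)},
            "potency_ratio_50": ratio(self.ratio_50),
            "potency_ratio_max": None
            if self.ratio_max is None
            else ratio(self.ratio_max),
            "max_effect_level": self.max_effect_level,
            "constancy_gtest": None
            if self.gtest is None
            else {
                "g_stat": self.gtest.g_stat,
                "p_value": self.gtest.p_value,
                "table": self.gtest.table.tolist(),
                "continuity_adjusted": self.gtest.continuity_adjusted,
            },
            "isobole_linear": self.isobole_linear,
            "escalation": {
                "mean_effect": self.escalation.mean_effect,
                "se": self.escalation.se,
                "t_stat": self.escalation.t_stat,
                "p_value": self.escalation.p_value,
                "level": self.escalation.level,
                "alpha": self.escalation.alpha,
            },
            "assessment_50": assessment(self.assessment_50),
            "assessment_escalated": assessment(self.assessment_escalated),
            "final_verdict": self.final_verdict,
        }


def analyze_records(
    records: Iterable[WellRecord],
    agent_a: str,
    agent_b: str,
    combo: tuple[float, float] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
    alpha: float = 0.05,
    blank: float = 0.0,
) -> SynergyAnalysis:
    """Run the full isobolographic analysis on raw well records.

    ``combo`` optionally pins the combination dose pair when the plate
    carries several.  ``seed`` drives the bootstrap; identical seeds give
    identical results.
    """
    viab = normalize(records, blank=blank)
    curve_a = build_effect_curve(viab, agent_a)
    curve_b = build_effect_curve(viab, agent_b)
    fit_a = fit_linear(curve_a)
    fit_b = fit_linear(curve_b)
    combo_obs = combination_observation(
        viab,
        agent_a,
        agent_b,
        dose_a=None if combo is None else combo[0],
        dose_b=None if combo is None else combo[1],
    )

    escalation = escalate_effect_level(combo_obs, alpha=alpha)
    e_max = max_common_effect(curve_a, curve_b)
    e_star = escalation.level
    if e_star > e_max:
        clamped = float(math.floor(e_max))
        logger.warning(
            "escalated level %.0f%% exceeds the maximum common observed "
            "effect %.1f%%; clamping to %.0f%%",
            e_star,
            e_max,
            clamped,
        )
        e_star = clamped

    levels = sorted({50.0, float(e_max), float(e_star)})
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    # non-strict: the max-common level sits on the boundary of the observed
    # range and may be bootstrap-unreliable; the verdict levels must exist
    eds_a = bootstrap_ed_multi(
        curve_a, levels, n_boot=n_boot, seed=seed_a, ci_level=ci_level, strict=False
    )
    eds_b = bootstrap_ed_multi(
        curve_b, levels, n_boot=n_boot, seed=seed_b, ci_level=ci_level, strict=False
    )
    for level in (50.0, float(e_star)):
        for agent, eds in ((agent_a, eds_a), (agent_b, eds_b)):
            if level not in eds:
                raise UnreliableBootstrap(
                    f"agent {agent!r}: bootstrap unreliable at required "
                    f"effect level {level:g}%"
                )

    ratio_50 = potency_ratio(eds_a[50.0], eds_b[50.0], ci_level=ci_level)
    ratio_max = None
    gtest = None
    isobole_linear = None
    if float(e_max) in eds_a and float(e_max) in eds_b:
        ratio_max = potency_ratio(
            eds_a[float(e_max)], eds_b[float(e_max)], ci_level=ci_level
        )
        gtest = constancy_gtest(ratio_50, ratio_max)
        isobole_linear = bool(gtest.p_value >= alpha)
        if not isobole_linear:
            logger.info(
                "potency ratio varies with effect level (G=%.3g, p=%.3g); "
                "the linear additivity isobole is questionable",
                gtest.g_stat,
                gtest.p_value,
            )
    else:
        logger.warning(
            "bootstrap unreliable at the maximum common effect level "
            "%.4g%%; potency-ratio constancy not assessed",
            e_max,
        )

    a_dose, b_dose = combo_obs.dose_a, combo_obs.dose_b
    assessment_50 = classify_combination(
        eds_a[50.0], eds_b[50.0], a_dose, b_dose, ci_level=ci_level, gtest=gtest
    )
    assessment_esc = classify_combination(
        eds_a[float(e_star)],
        eds_b[float(e_star)],
        a_dose,
        b_dose,
        ci_level=ci_level,
        gtest=gtest,
    )

    return SynergyAnalysis(
        agent_a=agent_a,
        agent_b=agent_b,
        curve_a=curve_a,
        curve_b=curve_b,
        fit_a=fit_a,
        fit_b=fit_b,
        combination=combo_obs,
        ed50_a=eds_a[50.0],
        ed50_b=eds_b[50.0],
        ratio_50=ratio_50,
        ratio_max=ratio_max,
        max_effect_level=float(e_max),
        gtest=gtest,
        isobole_linear=isobole_linear,
        escalation=escalation,
        assessment_50=assessment_50,
        assessment_escalated=assessment_esc,
    )
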