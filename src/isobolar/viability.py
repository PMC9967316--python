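"""Absorbance normalisation and dose-effect curve assembly.

Raw OD450 absorbances are normalised per plate against the mean of that
plate's untreated control wells: viability% = 100 * A / mean(A_control),
and the effect of a treatment is defined as the percent reduction in
viability, effect% = 100 - viability%.  Effects are deliberately not
clamped: a proliferation-promoting treatment (e.g. a low-dose opioid
agonist) yields a negative effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay_io import WellRecord

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """A plate cannot be normalised (no controls, or non-positive control
    mean)."""


@dataclass
class EffectCurve:
    """Per-agent dose grid with replicate effect values.

    ``doses`` are strictly increasing (µM); ``effects[j]`` holds the
    replicate effect values (% points) at ``doses[j]``; ``mean_effect`` and
    ``se`` are the per-dose mean and standard error (sample SD / sqrt(n));
    SE is NaN where fewer than two replicates exist.
    """

    agent: str
    doses: np.ndarray
    effects: list[np.ndarray]
    mean_effect: np.ndarray = field(default=None)  # type: ignore[assignment]
    se: np.ndarray = field(default=None)  # type: ignore[assignment]
    n: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.ndim != 1 or len(self.doses) != len(self.effects):
            raise ValueError("doses and effects must have matching lengths")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        self.effects = [np.asarray(e, dtype=float) for e in self.effects]
        if self.mean_effect is None:
            self.mean_effect = np.array([e.mean() for e in self.effects])
        else:
            self.mean_effect = np.asarray(self.mean_effect, dtype=float)
        if self.n is None:
            self.n = np.array([len(e) for e in self.effects], dtype=int)
        else:
            self.n = np.asarray(self.n, dtype=int)
        if self.se is None:
            self.se = np.array(
                [
                    e.std(ddof=1) / math.sqrt(len(e)) if len(e) >= 2 else np.nan
                    for e in self.effects
                ]
            )
        else:
            self.se = np.asarray(self.se, dtype=float)

    @property
    def max_mean_effect(self) -> float:
        return float(self.mean_effect.max())

    def nonzero(self) -> "EffectCurve":
        """The curve restricted to strictly positive doses."""
        keep = self.doses > 0
        if keep.all():
            return self
        idx = np.flatnonzero(keep)
        return EffectCurve(
            agent=self.agent,
            doses=self.doses[idx],
            effects=[self.effects[i] for i in idx],
        )


@dataclass
class CombinationObservation:
    """Replicate effects observed for one fixed dose pair (a, b)."""

    agent_a: str
    agent_b: str
    dose_a: float
    dose_b: float
    effects: np.ndarray
    mean_effect: float = field(default=None)  # type: ignore[assignment]
    se: float = field(default=None)  # type: ignore[assignment]
    n: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.n is None:
            self.n = int(len(self.effects))
        if self.n < 2:
            raise ValueError(
                "a combination observation needs >= 2 replicates, got "
                f"{self.n}"
            )
        if self.mean_effect is None:
            self.mean_effect = float(self.effects.mean())
        if self.se is None:
            self.se = float(self.effects.std(ddof=1) / math.sqrt(self.n))
        lo, hi = self.effects.min(), self.effects.max()
        if not (lo - 1e-9 <= self.mean_effect <= hi + 1e-9):
            raise ValueError("mean effect outside replicate range")


def normalize(
    records: Iterable[WellRecord], blank: float = 0.0
) -> pd.DataFrame:
    """Per-plate control normalisation of raw absorbances.

    Returns a DataFrame with one row per well carrying ``viability_pct``
    (100 * A / control mean of the same plate) and ``effect_pct``
    (100 - viability).  ``blank`` is an optional background absorbance
    subtracted from every well before normalisation (default 0: off).

    Raises :class:`NormalizationError` for a plate without control wells or
    with non-positive blank-corrected control mean.
    """
    rows = [
        {
            "plate_id": r.plate_id,
            "condition_id": r.condition_id,
            "agent1": r.agent1,
            "dose1": r.dose1,
            "agent2": r.agent2,
            "dose2": r.dose2,
            "absorbance": r.absorbance,
            "replicate": r.replicate,
            "is_control": r.is_control,
        }
        for r in records
    ]
    if not rows:
        raise NormalizationError("no wells to normalise")
    df = pd.DataFrame(rows)
    df["absorbance_corr"] = df["absorbance"] - blank
    out = []
    for plate_id, plate in df.groupby("plate_id", sort=False):
        controls = plate.loc[plate["is_control"], "absorbance_corr"]
        if controls.empty:
            raise NormalizationError(f"plate {plate_id!r} has no control wells")
        ctrl_mean = float(controls.mean())
        if ctrl_mean <= 0:
            raise NormalizationError(
                f"plate {plate_id!r}: control mean {ctrl_mean:.4g} <= 0"
            )
        plate = plate.copy()
        plate["viability_pct"] = 100.0 * plate["absorbance_corr"] / ctrl_mean
        plate["effect_pct"] = 100.0 - plate["viability_pct"]
        out.append(plate)
    result = pd.concat(out, ignore_index=True)
    return result.drop(columns=["absorbance_corr"])


def _single_agent_mask(df: pd.DataFrame, agent: str) -> pd.Series:
    in_slot1 = (df["agent1"] == agent) & (df["dose1"] > 0) & (df["dose2"] == 0)
    in_slot2 = (df["agent2"] == agent) & (df["dose2"] > 0) & (df["dose1"] == 0)
    return in_slot1 | in_slot2


def build_effect_curve(viability: pd.DataFrame, agent: str) -> EffectCurve:
    """Group single-agent wells of ``agent`` by dose into an
    :class:`EffectCurve` (means, SEs, ascending doses).

    Wells where the agent appears in either dose slot with the other slot
    at zero are used; duplicate dose rows merge naturally.  A dose with a
    single replicate keeps its mean but gets an SE of NaN with a logged
    warning.
    """
    mask = _single_agent_mask(viability, agent)
    sub = viability.loc[mask].copy()
    if sub.empty:
        raise ValueError(f"no single-agent wells found for agent {agent!r}")
    sub["dose"] = np.where(sub["agent1"] == agent, sub["dose1"], sub["dose2"])
    doses = np.sort(sub["dose"].unique())
    effects = [
        sub.loc[sub["dose"] == d, "effect_pct"].to_numpy(dtype=float)
        for d in doses
    ]
    for d, e in zip(doses, effects):
        if len(e) < 2:
            logger.warning(
                "agent %s dose %g: single replicate; SE omitted", agent, d
            )
    return EffectCurve(agent=agent, doses=doses, effects=effects)


def combination_observation(
    viability: pd.DataFrame,
    agent_a: str,
    agent_b: str,
    dose_a: float | None = None,
    dose_b: float | None = None,
) -> CombinationObservation:
    """Collect replicate effects for the combination wells of a dose pair.

    If the plate contains a single combination dose pair the pair may be
    omitted; multiple pairs require an explicit (dose_a, dose_b).
    """
    mask = (
        (viability["agent1"] == agent_a)
        & (viability["agent2"] == agent_b)
        & (viability["dose1"] > 0)
        & (viability["dose2"] > 0)
    )
    swapped = (
        (viability["agent1"] == agent_b)
        & (viability["agent2"] == agent_a)
        & (viability["dose1"] > 0)
        & (viability["dose2"] > 0)
    )
    sub = viability.loc[mask | swapped].copy()
    if sub.empty:
        raise ValueError(
            f"no combination wells for agents {agent_a!r} + {agent_b!r}"
        )
    is_fwd = sub["agent1"] == agent_a
    sub["dose_a"] = np.where(is_fwd, sub["dose1"], sub["dose2"])
    sub["dose_b"] = np.where(is_fwd, sub["dose2"], sub["dose1"])
    if dose_a is not None and dose_b is not None:
        sub = sub[(sub["dose_a"] == dose_a) & (sub["dose_b"] == dose_b)]
        if sub.empty:
            raise ValueError(
                f"no combination wells at ({dose_a}, {dose_b})"
            )
    else:
        pairs = sub[["dose_a", "dose_b"]].drop_duplicates()
        if len(pairs) > 1:
            raise ValueError(
                "multiple combination dose pairs present; specify "
                "(dose_a, dose_b) explicitly: "
                + ", ".join(
                    f"({p.dose_a:g}, {p.dose_b:g})"
                    for p in pairs.itertuples(index=False)
                )
            )
        dose_a = float(pairs.iloc[0, 0])
        dose_b = float(pairs.iloc[0, 1])
    return CombinationObservation(
        agent_a=agent_a,
        agent_b=agent_b,
        dose_a=float(dose_a),
        dose_b=float(dose_b),
        effects=sub["effect_pct"].to_numpy(dtype=float),
    )
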