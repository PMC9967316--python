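import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isobolar.viability import EffectCurve

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_linear_curve(
    slope: float,
    doses,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
    agent: str = "agent",
) -> EffectCurve:
    """Effect curve sampled from a linear truth effect = slope * dose with
    additive Gaussian noise on each replicate."""
    doses = np.asarray(doses, dtype=float)
    rng = rng or np.random.default_rng(0)
    effects = [
        slope * d + (noise_sd * rng.standard_normal(n_replicates) if noise_sd else np.zeros(n_replicates))
        for d in doses
    ]
    return EffectCurve(agent=agent, doses=doses, effects=effects)


def random_monotone_curve(rng: np.random.Generator, n_points: int = 5) -> EffectCurve:
    """Random strictly increasing dose/effect curve with replicates equal
    to the node value (deterministic means)."""
    doses = np.sort(rng.uniform(1.0, 100.0, size=n_points))
    while np.any(np.diff(doses) < 1e-3):
        doses = np.sort(rng.uniform(1.0, 100.0, size=n_points))
    effects = np.cumsum(rng.uniform(1.0, 25.0, size=n_points))
    return EffectCurve(
        agent="rand",
        doses=doses,
        effects=[np.array([e, e]) for e in effects],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
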