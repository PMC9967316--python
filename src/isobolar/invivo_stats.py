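"""Tumor-volume computation and treatment-group comparison statistics.

Caliper pairs become volumes via V = 1/2 * L * W^2 (mm^3).  Two groups are
compared with the pooled-variance independent t-test; more than two with
one-way ANOVA followed by pairwise post-hoc t-tests under Bonferroni
adjustment over the number of pairwise tests.  The comparison endpoint is
the volume at a chosen day (default: the last day measured in every
group), with nearest-day matching within a +/- 1 day tolerance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay_io import TumorMeasurement

logger = logging.getLogger(__name__)


@dataclass
class TumorSeries:
    """Per-animal growth series: ordered (day, volume mm^3) pairs."""

    animal_id: str
    group: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(
                f"animal {self.animal_id!r}: days must be strictly increasing"
            )
        if np.any(self.volumes <= 0):
            raise ValueError(f"animal {self.animal_id!r}: volumes must be > 0")


@dataclass
class AnovaResult:
    """One-way ANOVA across all groups at the endpoint day."""

    groups: tuple[str, ...]
    day: int
    f_stat: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    """Pairwise endpoint comparison with Bonferroni-adjusted p-value."""

    group_a: str
    group_b: str
    day: int
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    percent_difference: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("adjusted p-value cannot be below the raw one")


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """V = 1/2 * L * W^2 with L >= W enforced by swapping."""
    length, width = float(length_mm), float(width_mm)
    if length <= 0 or width <= 0:
        raise ValueError("caliper dimensions must be > 0")
    if width > length:
        length, width = width, length
    return 0.5 * length * width * width


def bonferroni(p_value: float, n_comparisons: int) -> float:
    """min(1, p * m); never decreases a p-value."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p_value * n_comparisons)


def volumes_frame(measurements: Iterable[TumorMeasurement]) -> pd.DataFrame:
    """Tidy frame of animal_id, group, day, volume (mm^3)."""
    rows = [
        {
            "animal_id": m.animal_id,
            "group": m.group,
            "day": m.day,
            "volume": tumor_volume(m.length_mm, m.width_mm),
        }
        for m in measurements
    ]
    if not rows:
        raise ValueError("no measurements supplied")
    return pd.DataFrame(rows)


def build_tumor_series(
    measurements: Iterable[TumorMeasurement],
) -> list[TumorSeries]:
    df = volumes_frame(measurements)
    out = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        out.append(
            TumorSeries(
                animal_id=str(animal),
                group=str(group),
                days=sub["day"].to_numpy(),
                volumes=sub["volume"].to_numpy(),
            )
        )
    return out


def _endpoint_day(df: pd.DataFrame) -> int:
    """Last day measured in every group (min of per-group maxima);
    nearest-day matching tolerates schedule jitter in the other groups."""
    return int(df.groupby("group")["day"].max().min())


def _group_endpoint_values(
    df: pd.DataFrame, day: int, tolerance: int = 1
) -> dict[str, np.ndarray]:
    """Per group, one volume per animal at the measurement day nearest to
    ``day`` within ``tolerance``; animals with no measurement in the window
    are dropped."""
    values: dict[str, np.ndarray] = {}
    for group, sub in df.groupby("group", sort=True):
        vols = []
        for _, animal in sub.groupby("animal_id"):
            gap = (animal["day"] - day).abs()
            nearest = gap.idxmin()
            if gap.loc[nearest] <= tolerance:
                vols.append(float(animal.loc[nearest, "volume"]))
        if vols:
            values[str(group)] = np.asarray(vols)
    return values


def percent_difference(
    measurements: Iterable[TumorMeasurement] | pd.DataFrame,
    reference_group: str,
    other_group: str,
    day: int | None = None,
    tolerance: int = 1,
) -> float:
    """100 * (mean_other - mean_reference) / mean_reference at the endpoint
    day; negative values mean a reduction versus the reference group."""
    df = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else volumes_frame(measurements)
    )
    if day is None:
        day = _endpoint_day(df)
    values = _group_endpoint_values(df, day, tolerance)
    for g in (reference_group, other_group):
        if g not in values:
            raise ValueError(f"group {g!r} has no animals measured near day {day}")
    ref = values[reference_group].mean()
    other = values[other_group].mean()
    return 100.0 * (other - ref) / ref


def compare_groups(
    measurements: Iterable[TumorMeasurement] | pd.DataFrame,
    day: int | None = None,
    tolerance: int = 1,
    equal_var: bool = True,
) -> tuple[AnovaResult | None, list[GroupComparison]]:
    """Endpoint comparison of treatment groups.

    Two groups: a single independent t-test (pooled variance by default,
    Welch via ``equal_var=False``) with no multiplicity adjustment.  More
    than two: one-way ANOVA plus all pairwise t-tests with Bonferroni
    adjustment over the number of pairs.  Groups with fewer than two
    animals at the endpoint are excluded with a warning.
    """
    df = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else volumes_frame(measurements)
    )
    if day is None:
        day = _endpoint_day(df)
    values = _group_endpoint_values(df, day, tolerance)
    for group in [g for g, v in values.items() if len(v) < 2]:
        logger.warning(
            "group %r has < 2 animals at day %d; excluded", group, day
        )
        del values[group]
    groups = sorted(values)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 animals each")
    anova: AnovaResult | None = None
    if len(groups) > 2:
        f_stat, p_value = stats.f_oneway(*(values[g] for g in groups))
        anova = AnovaResult(
            groups=tuple(groups),
            day=day,
            f_stat=float(f_stat),
            p_value=float(p_value),
            n=int(sum(len(values[g]) for g in groups)),
        )
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    comparisons = []
    for ga, gb in pairs:
        a, b = values[ga], values[gb]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = stats.ttest_ind(a, b, equal_var=equal_var)
            t_stat, p_raw = float(t_stat), float(p_raw)
        comparisons.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                day=day,
                statistic=t_stat,
                p_raw=p_raw,
                p_adjusted=bonferroni(p_raw, m),
                n_comparisons=m,
                percent_difference=100.0 * (b.mean() - a.mean()) / a.mean(),
                n_a=len(a),
                n_b=len(b),
            )
        )
    return anova, comparisons
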