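"""Burst detection and inter-burst-interval (IBI) statistics.

A protein burst is detected on the repressor series with a two-threshold
hysteresis rule: an onset is recorded when R crosses ``theta_on`` upward
while the detector is armed, and the detector re-arms only once R has fallen
below ``theta_off``.  With bursts orders of magnitude above the inter-burst
floor the detection is insensitive to the exact thresholds; the defaults are
relative to the trace maximum (20% on, 5% off) so they track the
copy-number scaling of burst amplitudes.

Regularity of a burst train is the mean IBI divided by the sample standard
deviation of the IBIs — the inverse coefficient of variation.  A perfectly
periodic train has infinite regularity; a Poisson (exponential-interval)
train has regularity 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ssa import Trajectory

__all__ = [
    "BurstTrain", "RegularityResult", "default_thresholds", "detect_bursts",
    "interburst_intervals", "regularity", "regularity_result",
    "analyze_trajectory", "replicate_summary",
]

MIN_IBIS_RELIABLE = 10  # shorter trains are flagged, not suppressed


@dataclass
class BurstTrain:
    onsets: np.ndarray          # hours, strictly increasing
    theta_on: float
    theta_off: float
    source: str = ""

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("burst onsets must be strictly increasing")

    @property
    def n_bursts(self) -> int:
        return int(self.onsets.size)


def default_thresholds(traj: Trajectory, on_frac: float = 0.2,
                       off_frac: float = 0.05) -> tuple[float, float]:
    mx = float(traj.series("R").max())
    return on_frac * mx, off_frac * mx


def detect_bursts(traj: Trajectory, theta_on: float, theta_off: float,
                  species: str = "R") -> BurstTrain:
    """Hysteresis burst detector on one species' series (default R)."""
    if not theta_on > theta_off >= 0:
        raise ValueError("need theta_on > theta_off >= 0")
    x = traj.series(species)
    armed = True
    onsets = []
    for i in range(x.size):
        if armed and x[i] >= theta_on:
            onsets.append(traj.times[i])
            armed = False
        elif not armed and x[i] <= theta_off:
            armed = True
    return BurstTrain(np.asarray(onsets), theta_on, theta_off,
                      source=str(traj.meta.get("seed", "")))


def interburst_intervals(train: BurstTrain) -> np.ndarray:
    """First differences of the onset times (hours)."""
    if train.n_bursts < 2:
        raise ValueError("need at least 2 burst onsets to form an interval")
    return np.diff(train.onsets)


@dataclass
class RegularityResult:
    """Eq.-(30)-style summary of one burst train.

    ``regularity`` is mean/SD with the sample (n−1) standard deviation.
    ``perfectly_periodic`` flags a zero-variance train, for which the ratio
    is reported as ``inf`` rather than crashing; ``reliable`` is False when
    fewer than ``MIN_IBIS_RELIABLE`` intervals were available.
    """

    ibis: np.ndarray
    mean_ibi: float
    sd_ibi: float
    regularity: float
    n_ibis: int
    perfectly_periodic: bool = False
    reliable: bool = True


def regularity(ibis: np.ndarray) -> float:
    """Mean IBI over sample standard deviation; ``inf`` for zero variance."""
    return regularity_result(ibis).regularity


def regularity_result(ibis: np.ndarray) -> RegularityResult:
    ibis = np.asarray(ibis, dtype=float)
    n = ibis.size
    if n < 2:
        raise ValueError("need at least 2 intervals for a regularity value")
    mean = float(ibis.mean())
    sd = float(ibis.std(ddof=1))
    if sd == 0.0:
        return RegularityResult(ibis, mean, 0.0, math.inf, n,
                                perfectly_periodic=True,
                                reliable=n >= MIN_IBIS_RELIABLE)
    return RegularityResult(ibis, mean, sd, mean / sd, n,
                            reliable=n >= MIN_IBIS_RELIABLE)


def analyze_trajectory(traj: Trajectory, theta_on: float | None = None,
                       theta_off: float | None = None) -> RegularityResult:
    """Detect bursts and summarise the IBIs of one trajectory.

    The first onset is discarded before differencing: it may fall inside the
    initial transient and would bias the interval statistics.
    """
    if theta_on is None or theta_off is None:
        theta_on, theta_off = default_thresholds(traj)
    train = detect_bursts(traj, theta_on, theta_off)
    if train.n_bursts < 3:
        raise ValueError(
            f"only {train.n_bursts} bursts detected; need >= 3 for intervals "
            "after discarding the first onset")
    ibis = np.diff(train.onsets[1:])
    return regularity_result(ibis)


def replicate_summary(values: np.ndarray) -> tuple[float, float]:
    """Across-replicate mean and standard error of per-replicate statistics
    (not pooled intervals)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    if v.size == 1:
        return float(v[0]), math.nan
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))
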