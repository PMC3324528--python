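"""Synthetic inputs with known statistical structure.

Every generator here carries its own ground truth so downstream stages can
be tested without simulating the full circuit: a constitutive birth–death
network whose stationary law is Poisson(alpha/delta), renewal burst traces
with a chosen inter-burst-interval distribution, and mean-IBI-vs-copy-number
tables drawn from the first-passage curve with multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .circuit import ReactionChannel, ReactionNetwork
from .firstpassage import FirstPassageParams, predict_ibi
from .ssa import Trajectory

__all__ = [
    "constitutive_network", "pure_death_network", "RenewalTraceSpec",
    "renewal_intervals", "renewal_trace", "ibi_dataset",
]


def constitutive_network(alpha: float, delta: float) -> ReactionNetwork:
    """One-species birth–death network: ∅→X at ``alpha``, X→∅ at ``delta``.

    Stationary law is Poisson with mean alpha/delta (Fano factor 1), which
    makes it an analytic oracle for the stochastic engine.  ``delta`` = 0 is
    rejected (no stationary law).
    """
    if not (alpha > 0 and delta > 0):
        raise ValueError("need alpha > 0 and delta > 0")
    species = ("X",)
    channels = (
        ReactionChannel("birth", alpha, (), (1,)),
        ReactionChannel("death", delta, ("X",), (-1,)),
    )
    return ReactionNetwork(species, channels, np.zeros(1, dtype=np.int64))


def pure_death_network(x0: int, delta: float) -> ReactionNetwork:
    """X→∅ at rate ``delta`` from ``x0`` copies; the mean extinction time is
    the harmonic sum (1/delta) Σ_{j=1..x0} 1/j."""
    if x0 < 1 or delta <= 0:
        raise ValueError("need x0 >= 1 and delta > 0")
    return ReactionNetwork(("X",),
                           (ReactionChannel("death", delta, ("X",), (-1,)),),
                           np.array([x0], dtype=np.int64))


@dataclass(frozen=True)
class RenewalTraceSpec:
    """Baseline-zero trace with rectangular bursts at renewal times."""

    distribution: Literal["constant", "exponential", "gamma"]
    mean_ibi: float                 # hours; for gamma this is shape*scale
    shape: float = 1.0              # gamma only
    burst_height: float = 1000.0
    burst_width: float = 2.0        # hours; must stay below plausible IBIs
    horizon: float = 500.0
    seed: int = 0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if min(self.mean_ibi, self.burst_height, self.burst_width,
               self.horizon, self.dt) <= 0 or self.shape <= 0:
            raise ValueError("all renewal-trace parameters must be positive")


def _draw_interval(rng: np.random.Generator, spec: RenewalTraceSpec) -> float:
    if spec.distribution == "constant":
        return spec.mean_ibi
    if spec.distribution == "exponential":
        return float(rng.exponential(spec.mean_ibi))
    if spec.distribution == "gamma":
        return float(rng.gamma(spec.shape, spec.mean_ibi / spec.shape))
    raise ValueError(f"unknown distribution {spec.distribution!r}")


def renewal_intervals(spec: RenewalTraceSpec, n: int) -> np.ndarray:
    """Draw ``n`` intervals from the spec's renewal distribution — the
    ground truth behind a trace, usable directly for statistic calibration
    at sample sizes where a dense trace would be wasteful."""
    rng = np.random.default_rng(spec.seed)
    return np.asarray([_draw_interval(rng, spec) for _ in range(n)])


def renewal_trace(spec: RenewalTraceSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate the trace and return it with the true onset times.

    Intervals are drawn from the requested renewal distribution; bursts are
    rectangles of the given height and width on a zero baseline.  Raises if
    a drawn interval would overlap the previous burst.
    """
    rng = np.random.default_rng(spec.seed)
    onsets = []
    t = spec.mean_ibi  # first onset one typical interval in
    while t < spec.horizon:
        onsets.append(t)
        ibi = _draw_interval(rng, spec)
        if ibi <= spec.burst_width:
            raise ValueError("drawn interval overlaps the previous burst")
        t += ibi
    onsets_arr = np.asarray(onsets)
    times = np.arange(0.0, spec.horizon + 0.5 * spec.dt, spec.dt)
    x = np.zeros_like(times)
    for o in onsets_arr:
        i0 = int(np.searchsorted(times, o))
        i1 = int(np.searchsorted(times, o + spec.burst_width))
        x[i0:i1] = spec.burst_height
    counts = np.zeros((times.size, 9))
    counts[:, 7] = x  # R column of the canonical species order
    traj = Trajectory(times, counts,
                      meta={"engine": "renewal-fixture", "seed": spec.seed,
                            "t_end": spec.horizon, "dt": spec.dt})
    return traj, onsets_arr


def ibi_dataset(p: FirstPassageParams, N_values, noise_cv: float,
                n_reps: int, seed: int) -> pd.DataFrame:
    """Mean-IBI table drawn from the first-passage curve.

    Each replicate multiplies the curve value by lognormal noise with unit
    mean and coefficient of variation ``noise_cv``; the table reports the
    across-replicate mean per N.  Deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    N_arr = np.asarray(N_values, dtype=float)
    truth = predict_ibi(N_arr, p)
    if noise_cv == 0:
        mean_ibi = np.repeat(truth[None, :], 1, axis=0).mean(axis=0)
    else:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=(n_reps, N_arr.size))
        mean_ibi = (truth[None, :] * noise).mean(axis=0)
    return pd.DataFrame({"N": N_arr.astype(int), "mean_ibi": mean_ibi,
                         "true_ibi": truth})
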