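"""Exact stochastic simulation (Gillespie direct method) of a reaction network.

Each step draws an exponential waiting time at the total propensity and picks
a channel with probability proportional to its propensity, so sample paths
are exact realisations of the chemical master equation.  The default output
is a piecewise-constant record on a uniform time grid (dt = 0.05 h), which
bounds memory for runs that fire 10⁷–10⁸ reaction events; the full event log
is available on request for small runs and is produced in bounded chunks.

Reproducibility contract: identical ``(network, t_end, seed)`` give an
identical trajectory.  Replicate ``r`` of an experiment uses
``base_seed + r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numba
import numpy as np

from .circuit import ReactionNetwork, SPECIES

__all__ = ["Trajectory", "simulate_ssa", "simulate_ssa_events", "sample_on_grid"]

MAX_SEED = 2**31  # numba's legacy RNG seeding takes 32-bit values


@dataclass
class Trajectory:
    """Time-stamped species counts.

    ``counts`` has one row per time point, columns in ``species`` order.
    Stochastic trajectories hold integers (stored as float for uniformity
    with the rate-equation engine); ``meta`` carries provenance (parameters,
    seed, engine name, grid spacing).
    """

    times: np.ndarray
    counts: np.ndarray
    species: tuple[str, ...] = SPECIES
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.times.size, len(self.species)):
            raise ValueError("counts must be (n_times, n_species)")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("trajectories start at t = 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_tsv(self, path: str | Path) -> None:
        """Write the trace with a ``#``-commented reproducibility block."""
        header = "time_h\t" + "\t".join(self.species)
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            fh.write(header + "\n")
            for t, row in zip(self.times, self.counts):
                vals = "\t".join(f"{v:g}" for v in row)
                fh.write(f"{t:g}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Trajectory":
        meta: dict[str, Any] = {}
        rows = []
        species: tuple[str, ...] = SPECIES
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                elif line.startswith("time_h"):
                    species = tuple(line.split("\t")[1:])
                elif line:
                    rows.append([float(v) for v in line.split("\t")])
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1:], species, meta)


@numba.njit
def _ssa_grid_kernel(k, r1, r2, S, x0, t0, t_end, dt, seed, grid_offset, n_grid):
    """Direct-method SSA recording last-value-carried-forward on a uniform
    grid.  Grid index g corresponds to absolute time (grid_offset + g) * dt.
    Returns the grid block, the final state, the final time and the step
    count."""
    np.random.seed(seed)
    n_ch = k.shape[0]
    n_sp = x0.shape[0]
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    x = x0.copy()
    t = t0
    gi = 0
    a = np.zeros(n_ch)
    nsteps = 0
    while t < t_end:
        tot = 0.0
        for i in range(n_ch):
            ai = k[i]
            if r1[i] >= 0:
                ai *= x[r1[i]]
            if r2[i] >= 0:
                ai *= x[r2[i]]
            a[i] = ai
            tot += ai
        if tot <= 0.0:
            break  # absorbing state: hold constant to t_end
        tau = -np.log(1.0 - np.random.random()) / tot
        tnew = t + tau
        while gi < n_grid and (grid_offset + gi) * dt <= tnew:
            out[gi] = x
            gi += 1
        t = tnew
        u = np.random.random() * tot
        c = 0.0
        j = n_ch - 1
        for i in range(n_ch):
            c += a[i]
            if u <= c:
                j = i
                break
        for s in range(n_sp):
            x[s] += S[j, s]
        nsteps += 1
    while gi < n_grid:
        out[gi] = x
        gi += 1
    return out, x, t, nsteps


@numba.njit
def _ssa_event_kernel(k, r1, r2, S, x0, t0, t_end, seed, max_events):
    """Direct-method SSA logging every event, up to ``max_events`` (chunked
    streaming is handled by the caller).  Returns times, states, the state
    and time reached, and a flag: 0 done, 1 buffer full, 2 absorbed."""
    np.random.seed(seed)
    n_ch = k.shape[0]
    n_sp = x0.shape[0]
    times = np.empty(max_events)
    states = np.empty((max_events, n_sp), dtype=np.int64)
    x = x0.copy()
    t = t0
    a = np.zeros(n_ch)
    n = 0
    flag = 0
    while True:
        tot = 0.0
        for i in range(n_ch):
            ai = k[i]
            if r1[i] >= 0:
                ai *= x[r1[i]]
            if r2[i] >= 0:
                ai *= x[r2[i]]
            a[i] = ai
            tot += ai
        if tot <= 0.0:
            flag = 2
            break
        tau = -np.log(1.0 - np.random.random()) / tot
        if t + tau > t_end:
            t = t_end
            break
        t += tau
        u = np.random.random() * tot
        c = 0.0
        j = n_ch - 1
        for i in range(n_ch):
            c += a[i]
            if u <= c:
                j = i
                break
        for s in range(n_sp):
            x[s] += S[j, s]
        times[n] = t
        states[n] = x
        n += 1
        if n == max_events:
            flag = 1
            break
    return times[:n], states[:n], x, t, flag


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if not (0 <= seed < MAX_SEED):
        raise ValueError(f"seed must be in [0, 2^31), got {seed}")
    return seed


def simulate_ssa(network: ReactionNetwork, t_end: float, seed: int,
                 dt: float = 0.05) -> Trajectory:
    """Exact SSA sample path recorded on a uniform grid of spacing ``dt``.

    If the total propensity reaches zero the state is held constant to
    ``t_end``.  The same seed and inputs always reproduce the same path.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    seed = _check_seed(seed)
    k, r1, r2, S = network.to_arrays()
    n_grid = int(np.floor(t_end / dt)) + 1
    out, _, _, nsteps = _ssa_grid_kernel(
        k, r1, r2, S, network.initial_counts, 0.0, t_end, dt, seed, 0, n_grid)
    times = np.arange(n_grid) * dt
    meta = {"engine": "ssa-direct", "seed": seed, "dt": dt, "t_end": t_end,
            "n_events": int(nsteps)}
    if network.params is not None:
        meta["params"] = network.params
    return Trajectory(times, out.astype(float), network.species, meta)


def simulate_ssa_events(network: ReactionNetwork, t_end: float, seed: int,
                        max_events: int = 10_000_000,
                        chunk: int = 1_000_000) -> Trajectory:
    """Exact SSA sample path with every reaction event recorded.

    Events are accumulated in bounded chunks; a run exceeding ``max_events``
    raises rather than exhausting memory.  The record starts with the initial
    state at t = 0.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    seed = _check_seed(seed)
    k, r1, r2, S = network.to_arrays()
    x = network.initial_counts.copy()
    t = 0.0
    all_t = [np.zeros(1)]
    all_x = [x[None, :].copy()]
    total = 0
    chunk_seed = seed
    while True:
        times, states, x, t, flag = _ssa_event_kernel(
            k, r1, r2, S, x, t, t_end, chunk_seed, chunk)
        all_t.append(times)
        all_x.append(states)
        total += times.size
        if flag != 1 or t >= t_end:
            break
        if total > max_events:
            raise RuntimeError(f"event log exceeded max_events={max_events}")
        chunk_seed = (chunk_seed + 987_654_321) % MAX_SEED  # fresh stream per chunk
    meta = {"engine": "ssa-direct-events", "seed": seed, "t_end": t_end,
            "n_events": total}
    if network.params is not None:
        meta["params"] = network.params
    traj = Trajectory(np.concatenate(all_t),
                      np.concatenate(all_x).astype(float),
                      network.species, meta)
    return traj


def sample_on_grid(traj: Trajectory, dt: float) -> Trajectory:
    """Resample a trajectory on a uniform grid, last value carried forward.

    The grid spans [0, t_horizon] where the horizon is the trajectory's
    recorded end (its ``t_end`` metadata if present).  Idempotent at a fixed
    ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    horizon = float(traj.meta.get("t_end", traj.times[-1]))
    n_grid = int(np.floor(horizon / dt)) + 1
    grid = np.arange(n_grid) * dt
    if grid[-1] < horizon:  # keep the final state visible even for dt > t_end
        grid = np.append(grid, horizon)
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    idx = np.clip(idx, 0, traj.times.size - 1)
    meta = dict(traj.meta)
    meta["dt"] = dt
    meta["t_end"] = horizon
    return Trajectory(grid, traj.counts[idx], traj.species, meta)
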