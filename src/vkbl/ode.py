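"""Deterministic rate-equation model of the circuit.

The nine rate equations are generated from the same sixteen-channel table as
the stochastic engine (mass action: dx/dt = Sᵀ a(x)), so the two model
descriptions cannot drift apart.  Operator conservation
(D_A + D_A_bound = D_R + D_R_bound = N) is exact in the vector field; for
stability work the two bound-operator variables are eliminated, leaving a
7-dimensional reduced system whose Jacobian carries no structural zero
eigenvalues.

Two distinct critical values of the control parameter delta_R are exposed:

* ``find_hopf`` — the linear-stability boundary, where the leading complex
  eigenvalue pair of the reduced Jacobian crosses the imaginary axis
  (delta_R ≈ 0.0962 at the default rates).
* ``find_oscillation_onset`` — the onset of sustained large-amplitude
  oscillation seen by direct integration from the standard initial state
  (delta_R ≈ 0.087812 at the default rates).

The gap between them is the signature of the subcritical scenario: the
stable large limit cycle born at the Hopf point extends below it down to a
fold of cycles, and for delta_R between the fold and the crossing the fixed
point is locally stable yet generic initial conditions end up on the cycle
(no practical bistability — the fixed point's basin is tiny).  The onset,
not the eigenvalue crossing, is the boundary between steady-state and
oscillatory behaviour that a bifurcation scan or an experiment sees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuit import CircuitParameters, ReactionNetwork, SPECIES, build_network
from .ssa import Trajectory

__all__ = [
    "derivatives",
    "integrate_ode",
    "find_fixed_point",
    "reduced_jacobian",
    "leading_eigenvalue",
    "find_hopf",
    "find_oscillation_onset",
    "bifurcation_diagram",
    "BifurcationScan",
]

_I_DA, _I_DAB, _I_DR, _I_DRB = (SPECIES.index(s) for s in
                                ("D_A", "D_A_bound", "D_R", "D_R_bound"))
#: indices kept in the conservation-reduced system
_KEEP = [i for i in range(len(SPECIES)) if i not in (_I_DAB, _I_DRB)]


def _network_arrays(params: CircuitParameters):
    return build_network(params).to_arrays()


def _rhs_factory(params: CircuitParameters):
    """Vector field and analytic Jacobian of the full 9-variable system."""
    k, r1, r2, S = _network_arrays(params)
    ST = S.T.astype(float)

    def rhs(x: np.ndarray) -> np.ndarray:
        a = k.copy()
        m1 = r1 >= 0
        a[m1] *= x[r1[m1]]
        m2 = r2 >= 0
        a[m2] *= x[r2[m2]]
        return ST @ a

    def jac(x: np.ndarray) -> np.ndarray:
        n_ch, n_sp = S.shape
        da = np.zeros((n_ch, n_sp))
        for i in range(n_ch):
            if r1[i] >= 0 and r2[i] >= 0:
                da[i, r1[i]] = k[i] * x[r2[i]]
                da[i, r2[i]] = k[i] * x[r1[i]]
            elif r1[i] >= 0:
                da[i, r1[i]] = k[i]
        return ST @ da

    return rhs, jac


def derivatives(state: np.ndarray, params: CircuitParameters) -> np.ndarray:
    """Time derivative of every species (molecules/h) under mass action.

    Generated from the same channel table as the stochastic network, so a
    rate change moves both model descriptions identically.
    """
    x = np.asarray(state, dtype=float)
    if np.any(x < 0):
        raise ValueError("state must be non-negative")
    rhs, _ = _rhs_factory(params)
    return rhs(x)


def standard_initial_state(params: CircuitParameters) -> np.ndarray:
    """All operators free, no mRNA or protein — the canonical start."""
    return build_network(params).initial_counts.astype(float)


def integrate_ode(params: CircuitParameters, init: np.ndarray | None = None,
                  t_end: float = 1000.0, rtol: float = 1e-8,
                  atol: float = 1e-10, dt_out: float = 0.05) -> Trajectory:
    """Integrate the rate equations with a stiff-capable solver (LSODA).

    Output is sampled on a uniform grid of ``dt_out`` hours.  Raises on
    solver failure instead of returning a silently truncated trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rhs, jac = _rhs_factory(params)
    x0 = standard_initial_state(params) if init is None else np.asarray(init, float)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(lambda t, x: rhs(x), (0.0, t_end), x0, method="LSODA",
                    jac=lambda t, x: jac(x), rtol=rtol, atol=atol,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    meta = {"engine": "ode-lsoda", "rtol": rtol, "atol": atol, "t_end": t_end,
            "dt": dt_out, "params": params}
    return Trajectory(sol.t, sol.y.T, SPECIES, meta)


# ---------------------------------------------------------------------------
# fixed points and linear stability on the conservation-reduced system

def _expand(y: np.ndarray, N: float) -> np.ndarray:
    x = np.empty(len(SPECIES))
    x[_KEEP] = y
    x[_I_DAB] = N - x[_I_DA]
    x[_I_DRB] = N - x[_I_DR]
    return x


def find_fixed_point(params: CircuitParameters,
                     extra_starts: tuple[np.ndarray, ...] = ()) -> np.ndarray:
    """Non-negative root of the rate equations with operator conservation
    imposed; residual max-norm below 1e-10.

    Tries a bank of starting points (a generic interior guess, a long
    integration endpoint, plus any caller-provided starts) and returns the
    first converged non-negative root.
    """
    N = float(params.gene_copy)
    rhs, jac = _rhs_factory(params)

    def res(y):
        return rhs(_expand(y, N))[_KEEP]

    def res_jac(y):
        J = jac(_expand(y, N))
        Jr = J[np.ix_(_KEEP, _KEEP)].copy()
        Jr[:, _KEEP.index(_I_DA)] -= J[_KEEP, _I_DAB]
        Jr[:, _KEEP.index(_I_DR)] -= J[_KEEP, _I_DRB]
        return Jr

    def starts():
        yield np.array([0.9 * N, 0.9 * N, 5.0 * N, 2.0 * N, 2.0, 100.0, 300.0])
        for s in extra_starts:
            s = np.asarray(s, float)
            yield s[_KEEP] if len(s) == len(SPECIES) else s
        # last resort: relax towards the attractor first
        yield integrate_ode(params, t_end=2000.0, dt_out=50.0).counts[-1][_KEEP]

    for y0 in starts():
        sol = root(res, y0, jac=res_jac, method="hybr", tol=1e-13)
        y = sol.x
        if sol.success and np.all(y > -1e-9) and np.max(np.abs(res(y))) < 1e-10:
            return _expand(np.clip(y, 0.0, None), N)
    raise RuntimeError("fixed-point search failed from all starting points")


def reduced_jacobian(params: CircuitParameters, x: np.ndarray) -> np.ndarray:
    """7×7 Jacobian at a (full, 9-variable) state with the two bound-operator
    variables eliminated through the conservation laws."""
    _, jac = _rhs_factory(params)
    J = jac(np.asarray(x, float))
    Jr = J[np.ix_(_KEEP, _KEEP)].copy()
    Jr[:, _KEEP.index(_I_DA)] -= J[_KEEP, _I_DAB]
    Jr[:, _KEEP.index(_I_DR)] -= J[_KEEP, _I_DRB]
    return Jr


def leading_eigenvalue(params: CircuitParameters,
                       fixed_point: np.ndarray | None = None) -> complex:
    """Eigenvalue of the reduced Jacobian with the largest real part."""
    x = find_fixed_point(params) if fixed_point is None else fixed_point
    ev = np.linalg.eigvals(reduced_jacobian(params, x))
    return complex(ev[np.argmax(ev.real)])


def find_hopf(params: CircuitParameters, delta_lo: float, delta_hi: float,
              tol: float = 1e-5) -> float:
    """Linear-stability boundary: bisect delta_R for the zero crossing of the
    leading reduced-Jacobian eigenvalue real part at the fixed point.

    Requires a sign change on the bracket and verifies that the crossing pair
    is complex (a Hopf, not a saddle-node); raises otherwise.
    """
    def lead(d):
        return leading_eigenvalue(params.with_(delta_R=d))

    lo, hi = float(delta_lo), float(delta_hi)
    f_lo, f_hi = lead(lo), lead(hi)
    if f_lo.real * f_hi.real >= 0:
        raise ValueError("leading eigenvalue real part does not change sign "
                         f"on [{lo}, {hi}]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if lead(mid).real * f_lo.real > 0:
            lo = mid
        else:
            hi = mid
    crossing = 0.5 * (lo + hi)
    lam = lead(crossing)
    if abs(lam.imag) < 1e-6:
        raise RuntimeError("crossing eigenvalue is real: not a Hopf bifurcation")
    return crossing


def _post_transient_amplitude(params: CircuitParameters, t_end: float,
                              window: float, rtol: float) -> tuple[float, float]:
    """(max-min, mean) of R over the last ``window`` hours from the standard
    initial state."""
    traj = integrate_ode(params, t_end=t_end, rtol=rtol, dt_out=0.5)
    R = traj.series("R")
    m = traj.times >= t_end - window
    return float(R[m].max() - R[m].min()), float(R[m].mean())


def find_oscillation_onset(params: CircuitParameters, delta_lo: float,
                           delta_hi: float, tol: float = 1e-5,
                           t_end: float = 5000.0, window: float = 1000.0,
                           amplitude_threshold: float = 1.0,
                           rtol: float = 1e-8) -> float:
    """Critical delta_R at which sustained oscillation first appears.

    Bisects on whether the post-transient amplitude of R (last ``window``
    hours of a ``t_end``-hour integration from the standard initial state)
    exceeds ``amplitude_threshold`` molecules.  At the default rates and
    gene copy 1 this locates delta_R* = 0.087812, the steady-state /
    oscillatory boundary of the rate-equation model.
    """
    def oscillates(d):
        amp, _ = _post_transient_amplitude(params.with_(delta_R=d),
                                           t_end, window, rtol)
        return amp > amplitude_threshold

    lo, hi = float(delta_lo), float(delta_hi)
    if oscillates(lo) or not oscillates(hi):
        raise ValueError(f"bracket [{lo}, {hi}] does not straddle the onset")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class BifurcationScan:
    """Post-transient extrema of R and leading-eigenvalue real parts on a
    grid of the control parameter."""

    delta_R: np.ndarray
    R_max: np.ndarray
    R_min: np.ndarray
    max_re_eig: np.ndarray
    onset_estimate: float | None  # first grid value with finite amplitude

    def amplitude(self) -> np.ndarray:
        return self.R_max - self.R_min


def bifurcation_diagram(params: CircuitParameters, delta_grid: np.ndarray,
                        t_transient: float = 300.0, t_measure: float = 300.0,
                        rtol: float = 1e-8) -> BifurcationScan:
    """Sweep delta_R: integrate from the standard initial state, discard the
    transient, record max/min of R and the fixed point's leading eigenvalue.

    Per-point failures are recorded as NaN rather than aborting the scan.
    The subcritical signature is a discontinuous jump of the amplitude at the
    onset (no continuous growth from zero).
    """
    grid = np.asarray(delta_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("delta_R grid must be strictly increasing")
    n = grid.size
    R_max = np.full(n, np.nan)
    R_min = np.full(n, np.nan)
    max_re = np.full(n, np.nan)
    t_end = t_transient + t_measure
    for i, d in enumerate(grid):
        p = params.with_(delta_R=float(d))
        try:
            traj = integrate_ode(p, t_end=t_end, rtol=rtol, dt_out=0.1)
            R = traj.series("R")
            m = traj.times >= t_transient
            R_max[i], R_min[i] = R[m].max(), R[m].min()
            max_re[i] = leading_eigenvalue(p).real
        except (RuntimeError, ValueError):
            continue
    amp = R_max - R_min
    finite = np.where(amp > 1.0)[0]
    onset = float(grid[finite[0]]) if finite.size else None
    return BifurcationScan(grid, R_max, R_min, max_re, onset)
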