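"""Two-variable (R, C) quasi-steady-state reduction of the circuit.

All species except the repressor R and the complex C are fast: operators,
mRNAs and the activator A equilibrate to the instantaneous (R, C).  At the
operator quasi-steady state the binding/unbinding terms cancel from the
activator balance, which collapses to a single scalar equation

    beta_A * M_A(A) - gamma_C * A * R - delta_A * A = 0,

with occupancy fractions gamma X A / (theta + gamma A) feeding the mRNA
levels.  C never enters this balance, so the quasi-steady activator is a
function of R alone.  The slow field is then

    dR/dt = beta_R * M_R(A(R)) - gamma_C * A(R) * R + delta_A * C - delta_R * R
    dC/dt = gamma_C * A(R) * R - delta_A * C.

Both nullclines are explicit curves C(R), so they are sampled directly
(log-spaced in R to resolve the small-R corner where the fixed point sits)
and their intersection is polished with a two-dimensional root solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, root

from .circuit import CircuitParameters, SPECIES

__all__ = ["quasi_steady_A", "qss_reduce", "nullclines", "NullclineSet"]


def _fast_subsystem(params: CircuitParameters):
    """Occupancies, mRNA levels and the activator balance at fixed (R, C)."""
    p = params
    N = float(p.gene_copy)
    aA = p.effective_rate("alpha_A")
    aAp = p.effective_rate("alpha_A_prime")
    aR = p.effective_rate("alpha_R")
    aRp = p.effective_rate("alpha_R_prime")

    def occ_bound_A(A):  # activator-occupied fraction of the A operator
        return N * p.gamma_A * A / (p.theta_A + p.gamma_A * A)

    def occ_bound_R(A):
        return N * p.gamma_R * A / (p.theta_R + p.gamma_R * A)

    def M_A(A):
        DAb = occ_bound_A(A)
        return (aA * (N - DAb) + aAp * DAb) / p.delta_MA

    def M_R(A):
        DRb = occ_bound_R(A)
        return (aR * (N - DRb) + aRp * DRb) / p.delta_MR

    def A_balance(A, R):
        return p.beta_A * M_A(A) - p.gamma_C * A * R - p.delta_A * A

    return M_A, M_R, A_balance


def quasi_steady_A(params: CircuitParameters, R: float) -> float:
    """Quasi-steady activator number at repressor level R.

    The balance is positive at A = 0 (basal transcription keeps producing
    activator) and tends to −∞, so a root exists; the smallest non-negative
    root is returned.  Raises if the bracket search fails.
    """
    _, _, bal = _fast_subsystem(params)
    f0 = bal(0.0, R)
    if f0 == 0.0:
        return 0.0
    hi = 1.0
    for _ in range(200):
        if bal(hi, R) < 0.0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("no admissible non-negative quasi-steady A root")
    return brentq(lambda a: bal(a, R), 0.0, hi, xtol=1e-14, rtol=1e-15)


def qss_reduce(params: CircuitParameters
               ) -> Callable[[float, float], tuple[float, float]]:
    """Reduced vector field f(R, C) = (dR/dt, dC/dt)."""
    p = params
    _, M_R, _ = _fast_subsystem(params)

    def field(R: float, C: float) -> tuple[float, float]:
        A = quasi_steady_A(p, R)
        dR = p.beta_R * M_R(A) - p.gamma_C * A * R + p.delta_A * C - p.delta_R * R
        dC = p.gamma_C * A * R - p.delta_A * C
        return dR, dC

    return field


@dataclass
class NullclineSet:
    """Sampled zero sets of the reduced field and their intersection."""

    R: np.ndarray          # common R sample (log-spaced)
    C_dR0: np.ndarray      # C on the dR/dt = 0 curve
    C_dC0: np.ndarray      # C on the dC/dt = 0 curve
    fixed_point: tuple[float, float]
    delta_R: float


def nullclines(params: CircuitParameters, R_range: tuple[float, float],
               C_range: tuple[float, float] | None = None,
               n_samples: int = 400) -> NullclineSet:
    """Sample both nullclines over ``R_range`` and locate their intersection.

    Both zero sets are single-valued in R here: solving each defining
    equation for C gives

        dC/dt = 0  ⇒  C = gamma_C A(R) R / delta_A
        dR/dt = 0  ⇒  C = (gamma_C A(R) R + delta_R R − beta_R M_R(A(R))) / delta_A

    The intersection (the reduced fixed point) is bracketed on the sampled
    difference and polished with a 2-D root solve on the reduced field.
    Raises if no sign change lies inside the window.
    """
    p = params
    lo, hi = R_range
    if not (0 < lo < hi):
        raise ValueError("R_range must be positive and increasing")
    _, M_R, _ = _fast_subsystem(params)
    Rs = np.geomspace(lo, hi, n_samples)
    C_dC0 = np.empty(n_samples)
    C_dR0 = np.empty(n_samples)
    for i, R in enumerate(Rs):
        A = quasi_steady_A(p, R)
        C_dC0[i] = p.gamma_C * A * R / p.delta_A
        C_dR0[i] = (p.gamma_C * A * R + p.delta_R * R
                    - p.beta_R * M_R(A)) / p.delta_A
    diff = C_dR0 - C_dC0
    sign = np.sign(diff)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise RuntimeError("nullclines do not intersect inside the window")
    i = idx[0]
    R_star = brentq(
        lambda R: (p.delta_R * R
                   - p.beta_R * M_R(quasi_steady_A(p, R))) / p.delta_A,
        Rs[i], Rs[i + 1], xtol=1e-12)
    field = qss_reduce(params)
    sol = root(lambda z: field(z[0], z[1]),
               [R_star, p.gamma_C * quasi_steady_A(p, R_star) * R_star / p.delta_A],
               tol=1e-12)
    if not sol.success:
        raise RuntimeError("fixed-point polish failed")
    fp = (float(sol.x[0]), float(sol.x[1]))
    if C_range is not None:
        keep = (C_dC0 <= C_range[1]) | (C_dR0 <= C_range[1])
        Rs, C_dR0, C_dC0 = Rs[keep], C_dR0[keep], C_dC0[keep]
    return NullclineSet(Rs, C_dR0, C_dC0, fp, p.delta_R)
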