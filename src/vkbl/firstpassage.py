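"""Phenomenological first-passage model of the inter-burst interval.

Between bursts the system sits near the deterministic fixed point; a burst
fires when molecular noise kicks it over an escape barrier.  With the
barrier height B proportional to gene copy number N and Poisson noise
(STD ∝ √N), the mean escape time is tau_0 · exp(a √N) where a is the
barrier-to-noise ratio at N = 1, and the mean interval adds the
noise-independent burst duration T_B:

    T(N) = T_B + T_0 · exp(a · √N).

``fit_ibi_curve`` fits all three parameters to measured mean IBIs by
nonlinear least squares, multi-started over a grid of ``a`` to avoid the
flat-exponential local minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FirstPassageParams", "FitResult", "predict_ibi", "fit_ibi_curve"]


@dataclass(frozen=True)
class FirstPassageParams:
    T_B: float   # burst duration, hours
    T_0: float   # escape-time scale, hours
    a: float     # barrier height / noise SD at N = 1, dimensionless

    def __post_init__(self) -> None:
        if self.T_B < 0 or self.T_0 <= 0 or self.a < 0:
            raise ValueError("need T_B >= 0, T_0 > 0, a >= 0")


@dataclass
class FitResult:
    params: FirstPassageParams
    rss: float
    converged: bool
    covariance: np.ndarray
    residuals: np.ndarray


def predict_ibi(N, p: FirstPassageParams):
    """Mean inter-burst interval at gene copy number N (hours).

    Monotone non-decreasing in N for a >= 0.  Accepts scalars or arrays;
    N must be >= 1.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 1):
        raise ValueError("gene copy number must be >= 1")
    out = p.T_B + p.T_0 * np.exp(p.a * np.sqrt(N_arr))
    return float(out) if np.isscalar(N) or N_arr.ndim == 0 else out


def fit_ibi_curve(N_values, mean_ibis, weights=None,
                  a_grid=(0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0)
                  ) -> FitResult:
    """Least-squares fit of T(N) = T_B + T_0 exp(a √N) to mean IBIs.

    ``weights`` are optional 1-sigma uncertainties per point.  Requires at
    least four distinct N values (three parameters); raises on fewer or on
    non-convergence from every start.
    """
    N_arr = np.asarray(N_values, dtype=float)
    y = np.asarray(mean_ibis, dtype=float)
    if N_arr.shape != y.shape:
        raise ValueError("N_values and mean_ibis must have equal length")
    if np.unique(N_arr).size < 4:
        raise ValueError("need at least 4 distinct gene copy numbers")
    sigma = None if weights is None else np.asarray(weights, dtype=float)

    def model(N, T_B, T_0, a):
        return T_B + T_0 * np.exp(a * np.sqrt(N))

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    y_lo, y_hi = float(y.min()), float(y.max())
    for a0 in a_grid:
        # start T_0 from the N=1-ish level, T_B from the remainder
        T0_0 = max((y_hi - y_lo) / max(np.exp(a0 * np.sqrt(N_arr.max()))
                                       - np.exp(a0 * np.sqrt(N_arr.min())), 1e-9),
                   1e-3)
        TB_0 = max(y_lo - T0_0 * np.exp(a0 * np.sqrt(N_arr.min())), 0.0)
        try:
            popt, pcov = curve_fit(
                model, N_arr, y, p0=[TB_0, T0_0, a0], sigma=sigma,
                bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, 10.0]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(N_arr, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("first-passage fit failed to converge from all starts")
    popt, pcov, rss = best
    params = FirstPassageParams(float(popt[0]), float(max(popt[1], 1e-12)),
                                float(popt[2]))
    resid = model(N_arr, *popt) - y
    return FitResult(params, rss, True, pcov, resid)
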