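"""Rate-equation model: consistency with the reaction network, fixed points,
linear stability, and the two critical values of the control parameter."""

import numpy as np
import pytest

from vkbl import (
    SPECIES,
    bifurcation_diagram,
    build_network,
    default_parameters,
    derivatives,
    find_fixed_point,
    find_hopf,
    find_oscillation_onset,
    integrate_ode,
    leading_eigenvalue,
    propensity,
)
from vkbl.bursts import analyze_trajectory, detect_bursts
from vkbl.ode import standard_initial_state

IDX = {s: i for i, s in enumerate(SPECIES)}


def test_initial_transcription_rates(params05):
    """From free operators only the two basal channels produce mRNA."""
    x = standard_initial_state(params05)
    dx = derivatives(x, params05)
    assert dx[IDX["M_A"]] == pytest.approx(50.0)
    assert dx[IDX["M_R"]] == pytest.approx(0.01)


def test_operator_conservation_in_vector_field(params05, rng):
    for _ in range(10):
        x = rng.uniform(0, 100, size=9)
        dx = derivatives(x, params05)
        assert dx[IDX["D_A"]] + dx[IDX["D_A_bound"]] == pytest.approx(0, abs=1e-12)
        assert dx[IDX["D_R"]] + dx[IDX["D_R_bound"]] == pytest.approx(0, abs=1e-12)


def test_vector_field_is_generated_from_the_channel_table(params05, rng):
    """dx/dt must equal the stoichiometry-weighted channel propensities, so
    the stochastic and deterministic descriptions share one model."""
    net = build_network(params05)
    _, _, _, S = net.to_arrays()
    for _ in range(5):
        x = rng.uniform(0, 50, size=9)
        expected = S.T @ np.array([propensity(x, c) for c in net.channels])
        np.testing.assert_allclose(derivatives(x, params05), expected,
                                   rtol=1e-12, atol=1e-12)


def test_rate_perturbation_moves_both_descriptions_identically(rng):
    """Perturbing any single rate changes the ODE field exactly as predicted
    by the perturbed channel's propensity — no duplicated definitions."""
    base = default_parameters(0.07)
    x = rng.uniform(1, 30, size=9)
    for field_name in ("alpha_A_prime", "gamma_C", "beta_R", "delta_MR",
                       "theta_R", "delta_R"):
        bumped = base.with_(**{field_name: getattr(base, field_name) * 1.5})
        d_ode = derivatives(x, bumped) - derivatives(x, base)
        net_b, net_0 = build_network(bumped), build_network(base)
        _, _, _, S = net_0.to_arrays()
        d_prop = np.array([propensity(x, cb) - propensity(x, c0)
                           for cb, c0 in zip(net_b.channels, net_0.channels)])
        np.testing.assert_allclose(d_ode, S.T @ d_prop, rtol=1e-10, atol=1e-12)


class TestFixedPoint:
    def test_residual_conservation_and_nonnegativity(self, params05):
        fp = find_fixed_point(params05)
        assert np.max(np.abs(derivatives(fp, params05))) < 1e-10
        assert fp[IDX["D_A"]] + fp[IDX["D_A_bound"]] == pytest.approx(1.0)
        assert np.all(fp >= 0)

    def test_stable_below_onset(self, params05):
        assert leading_eigenvalue(params05).real < 0

    def test_matches_long_integration_limit(self, params05):
        traj = integrate_ode(params05, t_end=3000.0, dt_out=10.0)
        fp = find_fixed_point(params05)
        end = traj.counts[-1]
        assert np.all(np.abs(end - fp) <= 1e-4 * np.maximum(np.abs(fp), 1e-3))


def test_steady_state_below_onset(params05):
    traj = integrate_ode(params05, t_end=1000.0, dt_out=0.5)
    R = traj.series("R")
    m = traj.times >= 700.0
    amp = R[m].max() - R[m].min()
    assert amp < 0.01 * R[m].mean()


def test_restart_from_endpoint_stays_put(params05):
    end = integrate_ode(params05, t_end=1500.0, dt_out=10.0).counts[-1]
    again = integrate_ode(params05, init=end, t_end=200.0, dt_out=10.0).counts[-1]
    assert np.all(np.abs(again - end) <= 1e-4 * np.maximum(np.abs(end), 1e-3))


def test_periodic_bursts_above_onset_period_independent_of_init():
    p = default_parameters(0.2)
    def period(init):
        traj = integrate_ode(p, init=init, t_end=800.0, dt_out=0.1)
        res = analyze_trajectory(traj)
        return res.mean_ibi
    p1 = period(None)
    other = standard_initial_state(p) + np.array([0, 0, 0, 0, 5, 2, 40, 300, 100.0])
    p2 = period(other)
    assert abs(p1 - p2) / p1 < 0.01
    assert 10.0 < p1 < 100.0  # genuinely oscillating on the circadian-like scale


def test_hopf_crossing_is_a_complex_pair(params05):
    """The linear-stability boundary: a complex conjugate pair crosses with
    nonzero frequency, above the large-amplitude onset (subcritical)."""
    crossing = find_hopf(params05, 0.05, 0.12, tol=1e-5)
    assert 0.090 < crossing < 0.100
    lam = leading_eigenvalue(params05.with_(delta_R=crossing))
    assert abs(lam.imag) > 0.1
    assert leading_eigenvalue(params05.with_(delta_R=crossing + 0.01)).real > 0
    assert leading_eigenvalue(params05.with_(delta_R=crossing - 0.01)).real < 0


def test_hopf_requires_sign_change(params05):
    with pytest.raises(ValueError):
        find_hopf(params05, 0.02, 0.05)


def test_onset_robust_to_integration_tolerance(params05):
    """The oscillation-onset location must not depend on solver rtol."""
    a = find_oscillation_onset(params05, 0.08, 0.1, tol=1e-5, rtol=1e-8)
    b = find_oscillation_onset(params05, 0.08, 0.1, tol=1e-5, rtol=1e-6)
    assert abs(a - b) <= 1e-5


def test_bifurcation_scan_shows_subcritical_jump(params05):
    grid = np.array([0.05, 0.06, 0.07, 0.08, 0.085, 0.09, 0.1, 0.12, 0.15])
    scan = bifurcation_diagram(params05, grid)
    assert scan.delta_R.size == scan.R_max.size == scan.R_min.size == grid.size
    assert np.all(scan.R_max >= scan.R_min)
    amp = scan.amplitude()
    below = grid < 0.0878
    assert np.all(amp[below] < 0.01 * scan.R_max[below])
    # amplitude appears discontinuously: the first oscillatory point is
    # already a full-size burst cycle, not a small limit cycle
    first_osc = np.where(amp > 1.0)[0][0]
    assert amp[first_osc] > 500.0
    assert scan.onset_estimate == pytest.approx(0.09, abs=1e-12)
    # eigenvalue crossing sits inside the oscillatory side of the scan
    assert np.all(scan.max_re_eig[grid < 0.09] < 0)
    assert np.all(scan.max_re_eig[grid >= 0.1] > 0)


def test_bifurcation_scan_rejects_unsorted_grid(params05):
    with pytest.raises(ValueError):
        bifurcation_diagram(params05, np.array([0.1, 0.05]))


def test_integration_rejects_bad_horizon(params05):
    with pytest.raises(ValueError):
        integrate_ode(params05, t_end=0.0)
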