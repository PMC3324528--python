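"""Exactness and plumbing of the stochastic simulation engine.

The quantitative oracles are analytic properties of simple birth-death
processes: a constitutive gene has a Poisson stationary law (mean alpha/delta,
Fano factor 1), a pure-death process has a harmonic-sum mean extinction time,
and a channel at frozen propensity fires with exponential waiting times.
"""

import numpy as np
import pytest
from scipy import stats

from vkbl import (
    Trajectory,
    build_network,
    constitutive_network,
    default_parameters,
    pure_death_network,
    sample_on_grid,
    simulate_ssa,
    simulate_ssa_events,
)
from vkbl.circuit import ReactionChannel, ReactionNetwork


def _decorrelated(series, dt, spacing):
    step = max(1, int(round(spacing / dt)))
    return series[::step]


def test_constitutive_stationary_mean_and_fano():
    """Time-average matches alpha/delta; variance/mean matches Poisson."""
    net = constitutive_network(50.0, 1.0)
    traj = simulate_ssa(net, 2000.0, seed=11, dt=0.05)
    x = traj.counts[traj.times > 20.0, 0]  # discard relaxation to stationarity
    # subsample at 5 correlation times (tau = 1/delta = 1 h) for iid-like SEs
    xs = _decorrelated(x, 0.05, 5.0)
    n = xs.size
    se_mean = xs.std(ddof=1) / np.sqrt(n)
    assert abs(xs.mean() - 50.0) < 3 * se_mean
    fano = xs.var(ddof=1) / xs.mean()
    se_fano = np.sqrt(2.0 / n)  # normal-approximation SE of var/mean at Fano 1
    assert abs(fano - 1.0) < 3 * se_fano


def test_pure_death_mean_extinction_time():
    """Mean extinction time of X -> 0 from x0 copies is (1/d) * H(x0)."""
    x0, delta = 100, 1.0
    expected = sum(1.0 / j for j in range(1, x0 + 1)) / delta
    times = []
    for seed in range(200):
        traj = simulate_ssa_events(pure_death_network(x0, delta), 1000.0, seed)
        assert traj.counts[-1, 0] == 0
        times.append(traj.times[-1])
    times = np.asarray(times)
    se = times.std(ddof=1) / np.sqrt(times.size)
    assert abs(times.mean() - expected) < 3 * se


def test_waiting_times_exponential_at_frozen_propensity():
    """An isolated zero-order channel fires as a Poisson process."""
    rate = 1000.0
    net = ReactionNetwork(("X",),
                          (ReactionChannel("birth", rate, (), (1,)),),
                          np.zeros(1, dtype=np.int64))
    traj = simulate_ssa_events(net, 12.0, seed=5)
    waits = np.diff(traj.times)
    assert waits.size > 10_000
    _, p = stats.kstest(waits, "expon", args=(0, 1.0 / rate))
    assert p > 0.01


def test_same_seed_reproduces_trajectory(network05):
    a = simulate_ssa(network05, 50.0, seed=123)
    b = simulate_ssa(network05, 50.0, seed=123)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = simulate_ssa(network05, 50.0, seed=124)
    assert not np.array_equal(a.counts, c.counts)


def test_absorbing_state_held_constant():
    """No zero-order channel and zero counts: nothing can ever fire."""
    net = pure_death_network(1, 2.0)
    empty = ReactionNetwork(net.species, net.channels,
                            np.zeros(1, dtype=np.int64))
    traj = simulate_ssa(empty, 10.0, seed=0, dt=1.0)
    assert np.all(traj.counts == 0)
    assert traj.times[-1] == 10.0


def test_operator_conservation_along_full_model_path(network05):
    traj = simulate_ssa(network05, 200.0, seed=9)
    DA = traj.series("D_A") + traj.series("D_A_bound")
    DR = traj.series("D_R") + traj.series("D_R_bound")
    assert np.all(DA == 1) and np.all(DR == 1)
    assert np.all(traj.counts >= 0)


def test_event_and_grid_records_agree(network05):
    ev = simulate_ssa_events(network05, 20.0, seed=42)
    grid = simulate_ssa(network05, 20.0, seed=42, dt=0.05)
    regridded = sample_on_grid(ev, 0.05)
    np.testing.assert_array_equal(regridded.counts, grid.counts)


class TestSampleOnGrid:
    def _traj(self):
        times = np.array([0.0, 0.3, 1.1])
        counts = np.zeros((3, 9))
        counts[:, 7] = [5, 7, 2]
        return Trajectory(times, counts, meta={"t_end": 1.1})

    def test_last_value_carried_forward(self):
        g = sample_on_grid(self._traj(), 1.0)
        assert list(g.times) == [0.0, 1.0, 1.1]
        assert g.series("R")[0] == 5   # state at t=0
        assert g.series("R")[1] == 7   # latest event before t=1 was at 0.3

    def test_dt_larger_than_horizon(self):
        g = sample_on_grid(self._traj(), 10.0)
        assert list(g.times) == [0.0, 1.1]
        assert g.series("R")[-1] == 2

    def test_idempotent(self):
        g1 = sample_on_grid(self._traj(), 0.25)
        g2 = sample_on_grid(g1, 0.25)
        np.testing.assert_array_equal(g1.counts, g2.counts)
        np.testing.assert_array_equal(g1.times, g2.times)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            sample_on_grid(self._traj(), 0.0)


def test_trace_tsv_round_trip(tmp_path, network05):
    traj = simulate_ssa(network05, 10.0, seed=4, dt=0.5)
    path = tmp_path / "trace.tsv"
    traj.to_tsv(path)
    back = Trajectory.from_tsv(path)
    assert back.species == traj.species
    np.testing.assert_allclose(back.counts, traj.counts)
    assert back.meta["engine"] == "ssa-direct"


def test_input_validation(network05):
    with pytest.raises(ValueError):
        simulate_ssa(network05, -1.0, seed=0)
    with pytest.raises(ValueError):
        simulate_ssa(network05, 10.0, seed=2**31)
    with pytest.raises(ValueError):
        simulate_ssa(network05, 10.0, seed=0, dt=-0.1)
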