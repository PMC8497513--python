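"""Integrator, initialization and protocol scheduling."""

import numpy as np
import pytest

from recolorpoly import (
    Configuration,
    ProtocolSchedule,
    SimulationParams,
    init_random_walk,
    langevin_step,
    run_protocol,
    run_replicas,
)
from recolorpoly.dynamics import Integrator, random_walk_chain
from recolorpoly.recolor import mark_initial_states


def _small_params(**kw):
    defaults = dict(n_chromatin=40, n_proteins=3, box_side=20.0,
                    marked_lo=10, marked_hi=30, n_marked=8)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestInitRandomWalk:
    def test_counts_and_bond_lengths(self, rng):
        p = SimulationParams(n_chromatin=200, n_proteins=5, box_side=40.0,
                             marked_lo=80, marked_hi=120, n_marked=17)
        cfg = init_random_walk(p, rng)
        assert cfg.n_total == 205 and cfg.n_chromatin == 200
        lengths = cfg.bond_lengths()
        assert len(lengths) == 199
        assert lengths.max() < p.r0_fene
        assert abs(lengths.mean() - 1.0) < 0.1

    def test_deterministic_given_seed(self):
        p = _small_params()
        a = init_random_walk(p, np.random.default_rng(4))
        b = init_random_walk(p, np.random.default_rng(4))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_raw_walk_obeys_ideal_chain_statistics(self, rng):
        # <R_ee^2> = (N-1) b^2 for a freely jointed chain
        n, trials = 80, 400
        walks = [random_walk_chain(n, rng) for _ in range(trials)]
        r2 = [np.sum((w[-1] - w[0]) ** 2) for w in walks]
        mean = np.mean(r2)
        assert abs(mean / (n - 1) - 1.0) < 0.15

    def test_pushoff_removes_deep_overlaps(self, rng):
        from recolorpoly.forces import total_energy
        from recolorpoly.potentials import wca_energy

        p = _small_params()
        cfg = init_random_walk(p, rng)
        d = cfg.positions[:, None, :] - cfg.positions[None, :, :]
        d -= p.box_side * np.round(d / p.box_side)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        iu = np.triu_indices(cfg.n_total, 1)
        assert wca_energy(np.maximum(r[iu], 1e-3)).max() < 10.0 + 1e-6


class TestLangevinStep:
    def test_zero_temperature_zero_force_decays_velocity(self):
        p = SimulationParams(n_chromatin=1, n_proteins=0, box_side=20.0,
                             marked_lo=0, marked_hi=1, n_marked=0,
                             temperature=0.0, k_bend=0.0)
        cfg = Configuration(
            positions=np.array([[10.0, 10.0, 10.0]]),
            velocities=np.array([[1.0, -0.5, 0.25]]),
            species=np.zeros(1, np.uint8),
            states=np.zeros(1, np.uint8),
            box_side=20.0,
        )
        out = langevin_step(cfg, p, np.random.default_rng(0), n_steps=100)
        expected = cfg.velocities * np.exp(-100 * p.dt)
        np.testing.assert_allclose(out.velocities, expected, rtol=1e-9)

    def test_deterministic_given_seed(self, rng):
        p = _small_params()
        cfg = init_random_walk(p, rng)
        a = langevin_step(cfg, p, np.random.default_rng(5), n_steps=50)
        b = langevin_step(cfg, p, np.random.default_rng(5), n_steps=50)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_free_particles_reach_equipartition(self):
        """<KE>/bead -> (3/2) kBT for a dilute gas of WCA beads."""
        p = SimulationParams(n_chromatin=1, n_proteins=63, box_side=40.0,
                             marked_lo=0, marked_hi=1, n_marked=0, k_bend=0.0)
        rng = np.random.default_rng(21)
        cfg = init_random_walk(p, rng)
        integ = Integrator(cfg, p)
        integ.run(2000, rng)  # thermalize
        samples = []
        for _ in range(400):
            integ.run(25, rng)
            samples.append(integ.kinetic_energy_per_bead())
        assert abs(np.mean(samples) / 1.5 - 1.0) < 0.02


class TestProtocol:
    def test_no_binding_window_leaves_chain_unmodified(self):
        p = _small_params()
        sch = ProtocolSchedule(t_equil=100, t_bind=0, t_post=100,
                               sample_interval=20)
        traj, series = run_protocol(p, sch, seed=2)
        assert series.n_ub[-1] == 0
        assert np.all(series.n_ub == 0)

    def test_recolor_disabled_freezes_states(self):
        p = _small_params()
        sch = ProtocolSchedule(t_equil=100, t_bind=200, t_post=100,
                               recolor_enabled=False, sample_interval=20)
        traj, series = run_protocol(p, sch, seed=2)
        assert np.all(series.n_ub == 0)
        for _, _, _, states in traj.frames:
            assert np.count_nonzero(states & 1) == p.n_marked

    def test_ub_timeline_matches_protocol_phases(self):
        """No Ub before binding-on, non-decreasing during, frozen after."""
        p = _small_params(n_chromatin=60, marked_lo=20, marked_hi=40, n_marked=12,
                          box_side=22.0)
        sch = ProtocolSchedule(t_equil=100, t_bind=600, t_post=300,
                               sample_interval=20)
        traj, series = run_protocol(p, sch, seed=8)
        t = series.times
        assert np.all(series.n_ub[t <= 0] == 0)
        during = series.n_ub[(t > 0) & (t <= sch.t_bind)]
        assert np.all(np.diff(during) >= 0)
        after = series.n_ub[t > sch.t_bind]
        assert np.all(after == series.n_ub[-1])
        assert all(e.time <= sch.t_bind + 1e-9 for e in traj.events)

    def test_frame_zero_at_end_of_equilibration(self):
        p = _small_params()
        sch = ProtocolSchedule(t_equil=100, t_bind=100, t_post=0,
                               sample_interval=20, frame_interval=50)
        traj, _ = run_protocol(p, sch, seed=1)
        assert traj.frames[0][0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(traj.times) > 0)


class TestReplicas:
    def test_single_replica_matches_run_protocol(self):
        p = _small_params()
        sch = ProtocolSchedule(t_equil=50, t_bind=100, t_post=50, sample_interval=25)
        series = run_replicas(p, sch, n_replicas=1, base_seed=42)
        _, direct = run_protocol(p, sch, seed=42)
        assert np.array_equal(series[0].mean_density, direct.mean_density)

    def test_ensemble_reproducible_and_replicas_distinct(self):
        p = _small_params()
        sch = ProtocolSchedule(t_equil=50, t_bind=100, t_post=0, sample_interval=25)
        a = run_replicas(p, sch, n_replicas=3, base_seed=7)
        b = run_replicas(p, sch, n_replicas=3, base_seed=7)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.mean_density, s2.mean_density)
        assert not np.array_equal(a[0].mean_density, a[1].mean_density)
        assert not np.array_equal(a[1].rg2, a[2].rg2)
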