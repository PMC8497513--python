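"""The read-write state machine: marking, writer sets, recoloring sweeps."""

import numpy as np
import pytest

from recolorpoly import (
    Configuration,
    SimulationParams,
    bound_protein_positions,
    mark_initial_states,
    recolor_sweep,
    ub_fraction,
)
from recolorpoly.recolor import k27me3_count, ub_count
from recolorpoly.states import CHROMATIN, PROTEIN


def _chain_with_proteins(protein_offsets, n_chrom=12, box=40.0, states=None):
    """Straight chain along x with proteins at given offsets from bead 0."""
    pos = np.zeros((n_chrom + len(protein_offsets), 3))
    pos[:n_chrom, 0] = np.arange(n_chrom) * 0.97
    for k, off in enumerate(protein_offsets):
        pos[n_chrom + k] = off
    pos += box / 2.0
    species = np.concatenate(
        [np.full(n_chrom, CHROMATIN, np.uint8),
         np.full(len(protein_offsets), PROTEIN, np.uint8)]
    )
    if states is None:
        states = np.zeros(n_chrom, np.uint8)
    return Configuration(
        positions=np.mod(pos, box),
        velocities=np.zeros_like(pos),
        species=species,
        states=states,
        box_side=box,
    )


class TestMarkInitialStates:
    def test_default_geometry_places_85_marked_beads_in_window(self, rng):
        params = SimulationParams()
        states = mark_initial_states(params, rng)
        marked = np.nonzero(states & 1)[0]
        assert len(marked) == 85
        assert marked.min() >= 400 and marked.max() < 600
        assert np.all(states[(states & 1) == 0] == 0)

    def test_edge_counts(self, rng):
        p0 = SimulationParams(n_chromatin=50, marked_lo=10, marked_hi=30, n_marked=0)
        assert not np.any(mark_initial_states(p0, rng))
        pf = SimulationParams(n_chromatin=50, marked_lo=10, marked_hi=30, n_marked=20)
        states = mark_initial_states(pf, rng)
        assert np.all(states[10:30] == 1) and k27me3_count(states) == 20

    def test_deterministic_given_seed(self):
        params = SimulationParams()
        a = mark_initial_states(params, np.random.default_rng(9))
        b = mark_initial_states(params, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_chromatin=50, marked_lo=10, marked_hi=20, n_marked=15)


class TestBoundProteins:
    def test_protein_near_marked_bead_is_a_writer(self):
        params = SimulationParams(n_chromatin=12, n_proteins=1, box_side=40.0,
                                  marked_lo=0, marked_hi=12, n_marked=1)
        states = np.zeros(12, np.uint8)
        states[0] = 1
        cfg = _chain_with_proteins([[0.0, 1.0, 0.0]], states=states)
        assert list(bound_protein_positions(cfg, params)) == [0]

    def test_distant_protein_excluded(self):
        params = SimulationParams(n_chromatin=12, n_proteins=1, box_side=40.0,
                                  marked_lo=0, marked_hi=12, n_marked=1)
        states = np.zeros(12, np.uint8)
        states[0] = 1
        cfg = _chain_with_proteins([[0.0, 12.5, 0.0]], states=states)
        assert len(bound_protein_positions(cfg, params)) == 0

    def test_agrees_with_bruteforce_on_random_configs(self, rng):
        params = SimulationParams(n_chromatin=30, n_proteins=8, box_side=10.0,
                                  marked_lo=0, marked_hi=30, n_marked=10)
        for _ in range(10):
            pos = rng.uniform(0, 10.0, size=(38, 3))
            states = np.zeros(30, np.uint8)
            states[rng.choice(30, 10, replace=False)] = 1
            cfg = Configuration(
                positions=pos, velocities=np.zeros((38, 3)),
                species=np.array([CHROMATIN] * 30 + [PROTEIN] * 8, np.uint8),
                states=states, box_side=10.0,
            )
            got = set(bound_protein_positions(cfg, params))
            expect = set()
            for k in range(8):
                for m in np.nonzero(states & 1)[0]:
                    d = pos[30 + k] - pos[m]
                    d -= 10.0 * np.round(d / 10.0)
                    if np.dot(d, d) < params.rc_attr**2:
                        expect.add(k)
            assert got == expect


class TestRecolorSweep:
    def _params(self, **kw):
        defaults = dict(n_chromatin=12, n_proteins=1, box_side=40.0,
                        marked_lo=0, marked_hi=12, n_marked=1)
        defaults.update(kw)
        return SimulationParams(**defaults)

    def test_no_writer_in_range_writes_nothing(self, rng):
        params = self._params()
        states = np.zeros(12, np.uint8)
        states[0] = 1
        cfg = _chain_with_proteins([[0.0, 30.0, 0.0]], states=states)
        new_states, event = recolor_sweep(cfg, params, rng)
        assert event.n_written == 0 and np.array_equal(new_states, states)

    def test_neutral_bead_near_bound_protein_becomes_ub_only(self, rng):
        params = self._params()
        states = np.zeros(12, np.uint8)
        states[0] = 1  # protein binds here; bead 1 is neutral at ~1 sigma
        cfg = _chain_with_proteins([[0.0, 1.5, 0.0]], states=states)
        for _ in range(60):  # sweeps are random; bead 1 is selected eventually
            states2, _ = recolor_sweep(cfg, params, rng)
            cfg.states[:] = states2
        assert cfg.states[1] == 2  # UB without K27me3
        assert cfg.states[0] == 3  # marked bead now carries both

    def test_k27me3_never_erased_and_ub_monotone(self, rng):
        params = self._params(n_chromatin=20, marked_hi=20, n_marked=6)
        states = mark_initial_states(params, rng)
        cfg = _chain_with_proteins([[5.0, 1.0, 0.0]], n_chrom=20, states=states)
        prev_ub = 0
        for _ in range(30):
            new_states, event = recolor_sweep(cfg, params, rng)
            assert k27me3_count(new_states) == 6
            assert ub_count(new_states) >= prev_ub
            written = set(event.indices_written)
            newly = set(np.nonzero((new_states & 2) & ~(cfg.states & 2))[0])
            assert newly == written
            prev_ub = ub_count(new_states)
            cfg.states[:] = new_states

    def test_any_protein_mode_saturates_writing_radius(self, rng):
        """With an unconditional writer pinned by the chain, every bead within
        the writing radius ends up ubiquitinated (absorbing state)."""
        params = self._params(write_condition="any_protein", n_marked=0)
        cfg = _chain_with_proteins([[5.3, 1.0, 0.0]], states=np.zeros(12, np.uint8))
        for _ in range(200):
            cfg.states[:], _ = recolor_sweep(cfg, params, rng)
        d = cfg.positions[:12] - cfg.positions[12]
        d -= 40.0 * np.round(d / 40.0)
        within = np.linalg.norm(d, axis=1) < params.recolor_radius
        assert within.any()
        assert np.array_equal((cfg.states & 2) != 0, within)

    def test_bound_protein_mode_requires_engaged_writer(self, rng):
        # protein within writing radius of neutral beads but far from any mark
        params = self._params(n_marked=0)
        cfg = _chain_with_proteins([[5.3, 1.0, 0.0]], states=np.zeros(12, np.uint8))
        for _ in range(50):
            cfg.states[:], _ = recolor_sweep(cfg, params, rng)
        assert ub_count(cfg.states) == 0

    def test_permutation_sweep_selects_each_bead_once(self, rng):
        params = self._params(sweep_mode="permutation", n_marked=0,
                              write_condition="any_protein")
        cfg = _chain_with_proteins([[5.3, 1.0, 0.0]], states=np.zeros(12, np.uint8))
        _, event = recolor_sweep(cfg, params, rng)
        assert event.n_selected == 12


class TestUbFraction:
    @pytest.mark.parametrize(
        "states, expected",
        [
            (np.zeros(10, np.uint8), 0.0),
            (np.full(10, 2, np.uint8), 1.0),
            (np.array([3] * 85 + [0] * 915, np.uint8), 0.085),
        ],
    )
    def test_counting(self, states, expected):
        assert ub_fraction(states) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ub_fraction(np.empty(0, np.uint8))
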