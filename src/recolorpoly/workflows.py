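"""Higher-level experiment drivers built on the simulation core.

These wrap the common study designs — stiffness calibration of the neutral
fibre and the sustained-compaction protocol comparison — so that scripts
and tests run them identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Integrator, init_random_walk, run_replicas
from .observables import (
    EnsembleSummary,
    aggregate_replicas,
    bond_tangent_correlation,
    fit_persistence_length,
)
from .params import ProtocolSchedule, SimulationParams


def estimate_persistence_length(
    n_beads: int = 200,
    t_equil: float = 1.0e4,
    t_production: float = 1.0e5,
    seed: int = 0,
    k_bend: float = 3.0,
    sample_every: float = 10.0,
    s_max: int = 10,
    box_side: float = 60.0,
) -> tuple[float, np.ndarray]:
    """Persistence length of the neutral semiflexible chain, in sigma.

    Simulates a protein-free WCA+FENE chain with the given bending
    constant, equilibrates, then accumulates bond tangent-tangent
    correlations over the production window and fits
    ``<t_i . t_{i+s}> = exp(-s / l_p)`` over lags ``s = 1..s_max`` (bond
    spacing taken as one sigma).  Returns the fitted l_p and the
    correlation curve.
    """
    params = SimulationParams(
        n_chromatin=n_beads,
        n_proteins=0,
        box_side=box_side,
        k_bend=k_bend,
        marked_lo=0,
        marked_hi=n_beads,
        n_marked=0,
    )
    ss = np.random.SeedSequence(seed)
    init_ss, dyn_ss = ss.spawn(2)
    init_rng = np.random.Generator(np.random.PCG64(init_ss))
    dyn_rng = np.random.Generator(np.random.SFC64(dyn_ss))
    config = init_random_walk(params, init_rng)
    integ = Integrator(config, params)
    integ.run(round(t_equil / params.dt), dyn_rng)
    per = max(1, round(sample_every / params.dt))
    snapshots = []
    for _ in range(round(t_production / sample_every)):
        integ.run(per, dyn_rng)
        snapshots.append(config.chromatin_positions(unwrapped=True).copy())
    corr = bond_tangent_correlation(snapshots, s_max=s_max)
    return fit_persistence_length(corr), corr


@dataclass
class CompactionSummary:
    """Window-averaged squared-density landmarks of a protocol ensemble."""

    baseline: float  # mean density^2 over the last window before binding-on
    termination: float  # ... over the last window of the binding phase
    end: float  # ... over the final window of the post phase
    ensemble: EnsembleSummary
    n_replicas: int

    @property
    def retention(self) -> float:
        """density^2 at the end of the post phase relative to termination."""
        return self.end / self.termination

    @property
    def relaxation_to_baseline(self) -> float:
        """|end - baseline| / baseline."""
        return abs(self.end - self.baseline) / self.baseline


def compaction_experiment(
    params: SimulationParams,
    schedule: ProtocolSchedule,
    n_replicas: int,
    base_seed: int,
    window: float = 1000.0,
) -> CompactionSummary:
    """Run the binding protocol over replicas and summarize the density trace.

    The three landmarks are means of the ensemble-mean squared local
    density over trailing windows of length ``window`` (in tau) ending at
    binding-on (baseline), binding termination, and the end of the post
    phase.
    """
    series = run_replicas(params, schedule, n_replicas=n_replicas, base_seed=base_seed)
    summary = aggregate_replicas(series)
    t = summary.times
    d2 = summary.mean["density_sq"]

    def trailing(upto: float) -> float:
        m = (t > upto - window) & (t <= upto + 1e-9)
        if not m.any():
            raise ValueError("no samples in the requested window")
        return float(d2[m].mean())

    return CompactionSummary(
        baseline=trailing(0.0),
        termination=trailing(schedule.t_bind),
        end=trailing(schedule.t_bind + schedule.t_post),
        ensemble=summary,
        n_replicas=n_replicas,
    )


def scaled_compaction_params(
    n_chromatin: int = 300, n_proteins: int = 6, box_side: float = 60.0
) -> SimulationParams:
    """Desk-scale variant of the compaction system.

    The chain, marked window and binder count are scaled to ~30% of the
    full system (300 beads, ~25 marked in the proportional [120, 180)
    window, 6 proteins); every interaction constant keeps its stated value.
    """
    factor = n_chromatin / 1000.0
    return SimulationParams(
        n_chromatin=n_chromatin,
        n_proteins=n_proteins,
        box_side=box_side,
        marked_lo=int(400 * factor),
        marked_hi=int(600 * factor),
        n_marked=int(85 * factor),
    )
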