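"""Langevin dynamics, the binding protocol, and replica orchestration.

The integrator is the BAOAB splitting of Langevin dynamics: a velocity-
Verlet step whose momentum update is interleaved with an exact
Ornstein-Uhlenbeck thermostat sub-step, which satisfies fluctuation-
dissipation at the bath temperature and has a very small kinetic-
temperature bias at dt = 0.01 tau.  Random numbers come from three
independent, documented numpy streams per replica (initialization,
thermostat noise, recoloring), spawned from the replica seed, so
recoloring choices never perturb the thermostat noise sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ProtocolSchedule, SimulationParams
from .potentials import OverstretchError, minimum_image
from .recolor import RecolorEvent, mark_initial_states, recolor_sweep, ub_count
from .states import CHROMATIN, PROTEIN
from .system import Configuration

#: Verlet skin in sigma; rebuilt when any bead moves more than skin/2.
DEFAULT_SKIN = 0.5


@dataclass
class Trajectory:
    """Stored frames of one protocol run (time, positions, images, states)."""

    frames: list = field(default_factory=list)
    params: SimulationParams | None = None
    schedule: ProtocolSchedule | None = None
    seed: int | None = None
    box_side: float = 0.0
    species: np.ndarray | None = None
    events: list = field(default_factory=list)

    def append(self, config: Configuration) -> None:
        if self.frames and config.time <= self.frames[-1][0]:
            raise ValueError("frame times must be strictly increasing")
        self.frames.append(
            (
                config.time,
                config.positions.copy(),
                config.image_counts.copy(),
                config.states.copy(),
            )
        )

    @property
    def times(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def configuration(self, k: int) -> Configuration:
        """Rebuild a full Configuration from frame ``k`` (zero velocities)."""
        t, pos, img, states = self.frames[k]
        return Configuration(
            positions=pos.copy(),
            velocities=np.zeros_like(pos),
            species=self.species.copy(),
            states=states.copy(),
            box_side=self.box_side,
            time=t,
            image_counts=img.copy(),
        )


def random_walk_chain(
    n: int, rng: np.random.Generator, bond_length: float = 1.0
) -> np.ndarray:
    """Freely jointed random-walk coordinates with fixed bond length."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.zeros((n, 3))
    pos[1:] = np.cumsum(bond_length * steps, axis=0)
    return pos


def _project_bonds(pos: np.ndarray, n_chrom: int, lo: float = 0.8, hi: float = 1.2):
    """Clamp chromatin bond lengths into [lo, hi] (works on unwrapped coords)."""
    for start in (0, 1):  # alternate even/odd bonds so shifts don't conflict
        b = np.arange(start, n_chrom - 1, 2)
        d = pos[b + 1] - pos[b]
        length = np.linalg.norm(d, axis=1)
        target = np.clip(length, lo, hi)
        shift = 0.5 * (length - target) / np.maximum(length, 1e-12)
        pos[b] += shift[:, None] * d
        pos[b + 1] -= shift[:, None] * d


def _push_off(
    pos: np.ndarray,
    n_chrom: int,
    box: float,
    rng: np.random.Generator | None = None,
    max_iter: int = 2500,
    target: float = 10.0,
) -> np.ndarray:
    """Remove overlaps with capped-displacement WCA descent.

    ``pos`` is treated as unwrapped; descent steps alternate with a bond
    projection that keeps chromatin bonds well inside the FENE range.
    Terminates once the largest WCA pair energy drops below ``target`` kBT
    (separation above ~0.72 sigma).
    """
    from .params import WCA_CUTOFF

    pos = pos.copy()
    n = len(pos)
    # separation at which the (shifted) WCA energy equals the target cap
    r_target = (2.0 / (1.0 + math.sqrt(target))) ** (1.0 / 6.0)
    maxp = 200 * max(n, 8)
    pair_i = np.empty(maxp, dtype=np.int32)
    pair_j = np.empty(maxp, dtype=np.int32)
    pair_eps = np.empty(maxp)
    pair_rc2 = np.empty(maxp)
    ncell = max(1, int(box / WCA_CUTOFF))
    head = np.full(ncell**3, -1, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    occ = np.empty(n, dtype=np.int64)
    states0 = np.zeros(n_chrom, dtype=np.uint8)
    wca2 = WCA_CUTOFF**2
    if rng is None:
        rng = np.random.default_rng(0)
    last_close = np.inf
    for it in range(max_iter):
        wrapped = np.mod(pos, box)
        npairs = _kernels.build_pairs(
            wrapped, box, states0, n_chrom, False, 1.0, 1.0, wca2, wca2, 0.0,
            pair_i, pair_j, pair_eps, pair_rc2, head, nxt, occ,
        )
        if npairs < 0:
            raise RuntimeError("pair buffer overflow during push-off")
        ii = pair_i[:npairs]
        jj = pair_j[:npairs]
        d = minimum_image(wrapped[ii] - wrapped[jj], box)
        r2 = np.einsum("ij,ij->i", d, d)
        close = r2 < r_target * r_target
        if not close.any():
            return pos
        # pairwise positional resolver: push each overlapping pair apart by
        # a fraction of its overlap depth (relaxation factor 0.3)
        r = np.sqrt(r2[close])
        dirs = np.where(
            r[:, None] > 1e-9, d[close] / np.maximum(r, 1e-9)[:, None], [1.0, 0.0, 0.0]
        )
        # push toward a 3% overshoot of the target so pairs actually cross it
        push = 0.3 * 0.5 * (1.03 * r_target - r)
        shift = np.zeros_like(pos)
        np.add.at(shift, ii[close], push[:, None] * dirs)
        np.add.at(shift, jj[close], -push[:, None] * dirs)
        pos += shift
        # frustrated clusters (interlocked hairpins) can deadlock the
        # resolver; a small jitter on the involved beads breaks the symmetry
        if it % 100 == 99:
            n_close = int(close.sum())
            if n_close >= last_close:
                involved = np.unique(np.concatenate([ii[close], jj[close]]))
                pos[involved] += rng.normal(scale=0.08, size=(len(involved), 3))
            last_close = n_close
        _project_bonds(pos, n_chrom)
    raise RuntimeError("could not resolve overlaps during initialization")


def init_random_walk(
    params: SimulationParams,
    rng: np.random.Generator,
    states: np.ndarray | None = None,
) -> Configuration:
    """Initial configuration: random-walk chain + uniformly placed proteins.

    The chromatin is laid down as a freely jointed random walk with bond
    length sigma centred in the box, proteins are placed uniformly at
    random, a short soft push-off removes overlaps (largest pair energy
    below 10 kBT), and velocities are drawn from the Maxwell-Boltzmann
    distribution at kBT.  Deterministic given the generator state.
    """
    n = params.n_total
    for _attempt in range(10):
        chain = random_walk_chain(params.n_chromatin, rng)
        chain += params.box_side / 2.0 - chain.mean(axis=0)
        pos = np.empty((n, 3))
        pos[: params.n_chromatin] = chain
        pos[params.n_chromatin :] = rng.uniform(
            0, params.box_side, size=(params.n_proteins, 3)
        )
        try:
            pos = _push_off(pos, params.n_chromatin, params.box_side, rng)
            break
        except RuntimeError:
            # rare tangled walk the resolver cannot open; draw a fresh one
            # (still deterministic: the generator state advances sequentially)
            continue
    else:
        raise RuntimeError("could not build an overlap-free initial state")
    img = np.floor(pos / params.box_side).astype(np.int64)
    pos = pos - img * params.box_side

    vel = rng.normal(scale=math.sqrt(params.temperature), size=(n, 3))
    species = np.concatenate(
        [
            np.full(params.n_chromatin, CHROMATIN, dtype=np.uint8),
            np.full(params.n_proteins, PROTEIN, dtype=np.uint8),
        ]
    )
    if states is None:
        states = np.zeros(params.n_chromatin, dtype=np.uint8)
    config = Configuration(
        positions=pos,
        velocities=vel,
        species=species,
        states=states,
        box_side=params.box_side,
        time=0.0,
        image_counts=img,
    )
    config.validate_bonds(params)
    return config


class Integrator:
    """Stateful Langevin engine bound to one Configuration (mutated in place)."""

    def __init__(
        self,
        config: Configuration,
        params: SimulationParams,
        binding_on: bool = False,
        skin: float = DEFAULT_SKIN,
    ) -> None:
        self.config = config
        self.params = params
        self.binding_on = binding_on
        self.skin = skin
        n = config.n_total
        cap = max(4096, 200 * n)
        self._pair_i = np.empty(cap, dtype=np.int32)
        self._pair_j = np.empty(cap, dtype=np.int32)
        self._pair_eps = np.empty(cap, dtype=np.float64)
        self._pair_rc2 = np.empty(cap, dtype=np.float64)
        ncell = max(1, int(config.box_side / (params.rc_attr + skin)))
        self._head = np.full(ncell**3, -1, dtype=np.int32)
        self._nxt = np.empty(n, dtype=np.int32)
        self._occ = np.empty(n, dtype=np.int64)
        self._npairs = np.array([-1], dtype=np.int64)
        self._ref_pos = np.empty((n, 3))
        self._bond_buf = np.empty((max(config.n_chromatin - 1, 1), 4))
        self._forces = np.zeros((n, 3))
        self._c1 = math.exp(-params.dt)  # gamma = m = 1
        self._c2 = math.sqrt(params.temperature * (1.0 - self._c1**2))

    def invalidate(self) -> None:
        """Force a neighbour-list rebuild (after states/positions changed)."""
        self._npairs[0] = -1

    def run(self, n_steps: int, rng: np.random.Generator, chunk: int = 1000) -> None:
        cfg = self.config
        p = self.params
        done = 0
        nc = cfg.n_chromatin
        while done < n_steps:
            m = min(chunk, n_steps - done)
            noise = rng.standard_normal((m, cfg.n_total, 3), dtype=np.float32)
            status = _kernels.run_chunk(
                cfg.positions,
                cfg.image_counts,
                cfg.velocities,
                cfg.states,
                nc,
                cfg.box_side,
                m,
                noise,
                p.dt,
                self._c1,
                self._c2,
                self.binding_on,
                p.eps_bind,
                p.eps_ub,
                p.rc_wca**2,
                p.rc_attr**2,
                p.k_fene,
                p.r0_fene,
                p.k_bend,
                self.skin,
                (self.skin / 2.0) ** 2,
                self._pair_i,
                self._pair_j,
                self._pair_eps,
                self._pair_rc2,
                self._head,
                self._nxt,
                self._occ,
                self._npairs,
                self._ref_pos,
                self._bond_buf,
                self._forces,
            )
            if status == _kernels.PAIR_OVERFLOW:
                raise RuntimeError("Verlet pair buffer overflow")
            if status > 0:
                raise OverstretchError(
                    f"FENE bond {status - 1} reached maximum extension at "
                    f"t={cfg.time:.2f}"
                )
            done += m
            cfg.time += m * p.dt

    def kinetic_energy_per_bead(self) -> float:
        """Unbiased kinetic energy per bead, in kBT.

        Uses the mid-cycle velocity ``v + (dt/2) f`` (the velocity after
        the first half-kick of the next step): in the BAOAB cycle that
        point samples the exact Maxwell-Boltzmann marginal, whereas the
        step-boundary velocity carries an O((omega dt)^2) deficit from the
        stiffest (bond) modes.
        """
        v = self.config.velocities + 0.5 * self.params.dt * self._forces
        return 0.5 * float(np.einsum("ij,ij->", v, v)) / self.config.n_total


def langevin_step(
    config: Configuration,
    params: SimulationParams,
    rng: np.random.Generator,
    binding_on: bool = False,
    n_steps: int = 1,
) -> Configuration:
    """Advance a copy of ``config`` by ``n_steps`` Langevin steps."""
    out = config.copy()
    integ = Integrator(out, params, binding_on=binding_on)
    integ.run(n_steps, rng)
    return out


@dataclass
class _Sampler:
    """Collects observable samples during a protocol run."""

    params: SimulationParams
    radius: float = 2.0
    times: list = field(default_factory=list)
    rg2: list = field(default_factory=list)
    mean_density: list = field(default_factory=list)
    n_ub: list = field(default_factory=list)

    def sample(self, config: Configuration, time: float) -> None:
        from .observables import local_density, radius_of_gyration_sq

        self.times.append(time)
        self.rg2.append(radius_of_gyration_sq(config.chromatin_positions()))
        dens = local_density(
            config.positions[: config.n_chromatin],
            radius=self.radius,
            box_side=config.box_side,
        )
        self.mean_density.append(float(dens.mean()))
        self.n_ub.append(ub_count(config.states))


def run_protocol(
    params: SimulationParams,
    schedule: ProtocolSchedule,
    seed: int,
    density_radius: float = 2.0,
):
    """Run equilibrate -> binding-on -> binding-off and collect observables.

    Phase 1 equilibrates with protein attraction off; phase 2 switches the
    protein-K27me3 attraction on and attempts a recoloring sweep every
    ``recolor_interval`` (when ``schedule.recolor_enabled``); phase 3
    switches protein attraction off and freezes the epigenetic states
    (Ub-Ub attraction persists).  Times are reported relative to the end of
    equilibration (equilibration samples have negative times); trajectory
    frame 0 is the end-of-equilibration configuration.

    Returns ``(trajectory, series)`` where ``series`` is an
    :class:`~recolorpoly.observables.ObservableSeries`; recoloring events
    are attached to the trajectory as ``trajectory.events``.
    """
    from .observables import ObservableSeries

    ss = np.random.SeedSequence(seed)
    init_ss, dyn_ss, rec_ss = ss.spawn(3)
    init_rng = np.random.Generator(np.random.PCG64(init_ss))
    dyn_rng = np.random.Generator(np.random.SFC64(dyn_ss))  # thermostat noise
    rec_rng = np.random.Generator(np.random.PCG64(rec_ss))

    states0 = mark_initial_states(params, init_rng)
    config = init_random_walk(params, init_rng, states=states0)
    config.time = -schedule.t_equil

    integ = Integrator(config, params, binding_on=False)
    sampler = _Sampler(params, radius=density_radius)
    traj = Trajectory(
        params=params,
        schedule=schedule,
        seed=seed,
        box_side=params.box_side,
        species=config.species.copy(),
    )

    dt = params.dt
    sample_steps = max(1, round(schedule.sample_interval / dt))
    frame_interval = schedule.frame_interval or 10 * schedule.sample_interval
    frame_steps = max(1, round(frame_interval / dt))
    recolor_steps = max(1, round(params.recolor_interval / dt))

    def advance(total_steps: int, *, recolor: bool, step0: int) -> int:
        """March ``total_steps``, sampling/recoloring on the global step grid."""
        step = step0
        end = step0 + total_steps
        while step < end:
            next_evts = [((step // sample_steps) + 1) * sample_steps]
            if recolor:
                next_evts.append(((step // recolor_steps) + 1) * recolor_steps)
            if frame_steps:
                next_evts.append(((step // frame_steps) + 1) * frame_steps)
            target = min(min(next_evts), end)
            integ.run(target - step, dyn_rng)
            step = target
            if recolor and step % recolor_steps == 0:
                new_states, event = recolor_sweep(config, params, rec_rng)
                if not np.array_equal(new_states, config.states):
                    config.states[:] = new_states
                    integ.invalidate()
                traj.events.append(event)
            if step % sample_steps == 0:
                sampler.sample(config, config.time)
            if step >= 0 and step % frame_steps == 0:
                traj.append(config)
        return step

    equil_steps = round(schedule.t_equil / dt)
    bind_steps = round(schedule.t_bind / dt)
    post_steps = round(schedule.t_post / dt)

    sampler.sample(config, config.time)
    step = advance(equil_steps, recolor=False, step0=-equil_steps)
    if not traj.frames:
        traj.append(config)  # frame 0: end of equilibration

    integ.binding_on = True
    step = advance(bind_steps, recolor=schedule.recolor_enabled, step0=step)

    integ.binding_on = False
    integ.invalidate()
    advance(post_steps, recolor=False, step0=step)

    series = ObservableSeries.from_samples(
        times=np.array(sampler.times),
        rg2=np.array(sampler.rg2),
        mean_density=np.array(sampler.mean_density),
        n_ub=np.array(sampler.n_ub, dtype=np.int64),
        replica_id=seed,
    )
    return traj, series


def run_replicas(
    params: SimulationParams,
    schedule: ProtocolSchedule,
    n_replicas: int,
    base_seed: int,
    density_radius: float = 2.0,
    keep_trajectories: bool = False,
):
    """Run independent replicas with seeds ``base_seed + k``.

    Returns a list of per-replica ObservableSeries (all on the same
    sampling grid); with ``keep_trajectories`` also a list of trajectories.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    series_list = []
    trajs = []
    for k in range(n_replicas):
        traj, series = run_protocol(
            params, schedule, seed=base_seed + k, density_radius=density_radius
        )
        series_list.append(series)
        if keep_trajectories:
            trajs.append(traj)
    if keep_trajectories:
        return series_list, trajs
    return series_list
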