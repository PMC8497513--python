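"""Simulation parameters and the binding/recoloring protocol schedule."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

WriteCondition = Literal["bound_protein", "any_protein"]
SweepMode = Literal["with_replacement", "permutation"]


@dataclass
class SimulationParams:
    """Every constant of the polymer model, in reduced units.

    Defaults are the model's stated values: a 1000-bead chromatin fibre
    (30 nm / 3 kbp per bead) with FENE bonds (k = 30 eps/sigma^2,
    R0 = 1.5 sigma), bending constant 3 kBT, 20 protein bridges, reader
    binding of 4 kBT and Ub-Ub self-attraction of 3 kBT, both with cutoff
    1.8 sigma, recoloring attempted every 10 Brownian times with a writing
    radius of 2 sigma (60 nm), and 85 marked beads placed in the index
    window [400, 600).

    ``write_condition`` selects how the ambiguous writing rule is resolved:
    ``"bound_protein"`` (default) requires the writer protein to be engaged
    with a K27me3 bead (within ``rc_attr`` of one); ``"any_protein"``
    accepts any protein within the writing radius.
    """

    n_chromatin: int = 1000
    n_proteins: int = 20
    box_side: float = 60.0
    dt: float = 0.01
    k_fene: float = 30.0
    r0_fene: float = 1.5
    k_bend: float = 3.0
    eps_bind: float = 4.0
    eps_ub: float = 3.0
    rc_wca: float = WCA_CUTOFF
    rc_attr: float = 1.8
    recolor_interval: float = 10.0
    recolor_radius: float = 2.0
    marked_lo: int = 400
    marked_hi: int = 600
    n_marked: int = 85
    n_replicas: int = 36
    base_seed: int = 0
    write_condition: WriteCondition = "bound_protein"
    sweep_mode: SweepMode = "with_replacement"
    temperature: float = 1.0  # kBT of the heat bath; 1 in reduced units

    def __post_init__(self) -> None:
        if self.n_chromatin < 1:
            raise ValueError("n_chromatin must be >= 1")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.rc_wca < self.rc_attr):
            raise ValueError("need rc_attr > rc_wca > 0")
        if not (0 <= self.marked_lo < self.marked_hi <= self.n_chromatin):
            raise ValueError("need 0 <= marked_lo < marked_hi <= n_chromatin")
        if not (0 <= self.n_marked <= self.marked_hi - self.marked_lo):
            raise ValueError("n_marked exceeds the marked index window")
        for name in ("k_fene", "k_bend", "eps_bind", "eps_ub"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r0_fene <= 0:
            raise ValueError("r0_fene must be positive")
        if self.recolor_interval <= 0 or self.recolor_radius <= 0:
            raise ValueError("recolor_interval and recolor_radius must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.write_condition not in ("bound_protein", "any_protein"):
            raise ValueError(f"unknown write_condition {self.write_condition!r}")
        if self.sweep_mode not in ("with_replacement", "permutation"):
            raise ValueError(f"unknown sweep_mode {self.sweep_mode!r}")

    @property
    def n_total(self) -> int:
        return self.n_chromatin + self.n_proteins

    def scaled(self, factor: float) -> "SimulationParams":
        """Return a copy with chain, marked window and protein count scaled.

        Used for desk-scale runs: bead counts and the marked window are
        scaled proportionally (rounded), every interaction constant is kept.
        """
        n = max(2, round(self.n_chromatin * factor))
        return replace(
            self,
            n_chromatin=n,
            n_proteins=max(1, round(self.n_proteins * factor)),
            marked_lo=round(self.marked_lo * factor),
            marked_hi=round(self.marked_hi * factor),
            n_marked=max(1, round(self.n_marked * factor)),
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ProtocolSchedule:
    """Durations (in tau) of the three protocol phases and sampling grid.

    Phase 1 equilibrates with protein binding off; phase 2 switches the
    protein-K27me3 attraction on and, if ``recolor_enabled``, attempts a
    recoloring sweep every ``recolor_interval``; phase 3 switches binding
    off again (Ub-Ub attraction persists) and recoloring stops.

    The default equilibration is a desk-scale 1e4 tau; production-scale
    equilibration (1e6 tau) is supported by simply passing it.
    """

    t_equil: float = 1.0e4
    t_bind: float = 2.0e4
    t_post: float = 1.0e4
    recolor_enabled: bool = True
    sample_interval: float = 25.0
    frame_interval: float | None = None  # None -> store frames every 10 samples

    def __post_init__(self) -> None:
        if min(self.t_equil, self.t_bind, self.t_post) < 0:
            raise ValueError("phase durations must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def t_total(self) -> float:
        return self.t_equil + self.t_bind + self.t_post

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
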