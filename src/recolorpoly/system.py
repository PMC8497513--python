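"""The instantaneous state of the simulated system."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams
from .potentials import minimum_image
from .states import CHROMATIN, PROTEIN


@dataclass
class Configuration:
    """Positions, velocities, species and epigenetic states of all beads.

    Beads are ordered chromatin first (indices ``0 .. n_chromatin-1``), then
    proteins.  ``positions`` are wrapped into ``[0, box_side)``;
    ``image_counts`` records how many times each coordinate has wrapped, so
    unwrapped coordinates — needed for the radius of gyration and bond
    statistics — are ``positions + image_counts * box_side``.
    ``states`` has one entry per *chromatin* bead.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    states: np.ndarray
    box_side: float
    time: float = 0.0
    image_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.uint8)
        self.states = np.ascontiguousarray(self.states, dtype=np.uint8)
        if self.image_counts is None:
            self.image_counts = np.zeros_like(self.positions, dtype=np.int64)
        self.image_counts = np.ascontiguousarray(self.image_counts, dtype=np.int64)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.positions.shape != (n, 3):
            raise ValueError("positions and velocities must be (n, 3)")
        if self.image_counts.shape != (n, 3):
            raise ValueError("image_counts must be (n, 3)")
        if len(self.species) != n:
            raise ValueError("species length inconsistent with positions")
        if len(self.states) != self.n_chromatin:
            raise ValueError("states must have one entry per chromatin bead")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if np.any(self.species[: self.n_chromatin] != CHROMATIN):
            raise ValueError("beads must be ordered chromatin first")

    @property
    def n_total(self) -> int:
        return len(self.positions)

    @property
    def n_chromatin(self) -> int:
        return int(np.count_nonzero(self.species == CHROMATIN))

    @property
    def n_proteins(self) -> int:
        return int(np.count_nonzero(self.species == PROTEIN))

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.image_counts * self.box_side

    def chromatin_positions(self, unwrapped: bool = True) -> np.ndarray:
        pos = self.unwrapped_positions() if unwrapped else self.positions
        return pos[: self.n_chromatin]

    def protein_positions(self) -> np.ndarray:
        return self.positions[self.n_chromatin :]

    def bond_lengths(self) -> np.ndarray:
        """Unwrapped consecutive chromatin bond lengths."""
        chain = self.chromatin_positions(unwrapped=True)
        return np.linalg.norm(np.diff(chain, axis=0), axis=1)

    def validate_bonds(self, params: SimulationParams) -> None:
        """Raise if any chromatin bond reached the FENE maximum extension."""
        lengths = self.bond_lengths()
        if lengths.size and float(lengths.max()) >= params.r0_fene:
            bad = int(np.argmax(lengths))
            raise ValueError(
                f"bond {bad} has length {lengths[bad]:.3f} >= r0_fene={params.r0_fene}"
            )

    def copy(self) -> "Configuration":
        return Configuration(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            states=self.states.copy(),
            box_side=self.box_side,
            time=self.time,
            image_counts=self.image_counts.copy(),
        )

    def displacement(self, i: int, j: int) -> np.ndarray:
        """Minimum-image displacement from bead i to bead j."""
        return minimum_image(self.positions[j] - self.positions[i], self.box_side)
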