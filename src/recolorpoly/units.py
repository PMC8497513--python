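"""Reduced-unit system of the chromatin polymer model.

The model is formulated in standard coarse-grained polymer units: the bead
diameter ``sigma`` is the unit of length, the thermal energy ``kBT`` the unit
of energy (so every well depth is quoted in kBT), and the bead mass and
friction coefficient are both one.  With that choice the Lennard-Jones time
``tau = sigma * sqrt(m / eps)`` and the Brownian time
``tau_B = gamma * sigma**2 / kBT`` (the time for a bead to diffuse its own
diameter) coincide and equal one simulation time unit.

Physically one bead represents 3 kbp of chromatin with a diameter of 30 nm,
so lengths convert to nanometres by multiplying by 30 and to genomic
coordinates by multiplying by 3 kbp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Attributes
    ----------
    sigma_nm : float
        Physical diameter of one bead in nanometres (default 30).
    sigma_kbp : float
        Genomic content of one bead in kilobase pairs (default 3).
    energy : float
        The energy unit; kBT is identified with the LJ epsilon, so 1.
    mass : float
        Bead mass in reduced units (1).
    gamma : float
        Friction coefficient of the Langevin bath in reduced units (1).
    """

    sigma_nm: float = 30.0
    sigma_kbp: float = 3.0
    energy: float = 1.0
    mass: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_nm", "sigma_kbp", "energy", "mass", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def tau(self) -> float:
        """LJ time sigma*sqrt(m/eps) in reduced units (sigma == 1)."""
        return math.sqrt(self.mass / self.energy)

    @property
    def tau_brownian(self) -> float:
        """Brownian time gamma*sigma^2/kBT in reduced units (sigma == 1)."""
        return self.gamma / self.energy

    def to_nm(self, length_sigma: float) -> float:
        """Convert a length from bead diameters to nanometres."""
        return length_sigma * self.sigma_nm

    def from_nm(self, length_nm: float) -> float:
        """Convert a length from nanometres to bead diameters."""
        return length_nm / self.sigma_nm

    def to_kbp(self, contour_sigma: float) -> float:
        """Convert a contour length in beads to kilobase pairs."""
        return contour_sigma * self.sigma_kbp


DEFAULT_UNITS = UnitSystem()
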