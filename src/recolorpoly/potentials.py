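"""Analytic pair, bond and bending potentials of the polymer model.

All functions accept scalars or numpy arrays and return energies in kBT.
Conventions:

* WCA — Lennard-Jones shifted up by eps/4 and truncated at 2^(1/6) sigma,
  so it is non-negative, purely repulsive and continuous at the cutoff.
* Attractive LJ — the *unshifted* 4 eps [(1/r)^12 - (1/r)^6] truncated at
  ``rc`` (default 1.8 sigma).  The shift is deliberately omitted so that
  the quoted well depths (4 kBT reader binding, 3 kBT Ub-Ub) are the true
  minimum values; the ~0.114 eps discontinuity at the cutoff is accepted,
  as is standard for truncated LJ fluids.
* FENE — the attractive finitely extensible bond term only; excluded
  volume between bonded neighbours comes from WCA acting on all pairs.
* Bending — k_bend (1 - cos alpha) with alpha the angle between
  consecutive bond tangents, so a straight chain costs nothing and a
  reversal costs 2 k_bend; this yields a persistence length of about
  k_bend sigma / kBT.
"""

from __future__ import annotations

import numpy as np

from .params import WCA_CUTOFF


class OverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension (integration blow-up)."""


def _as_positive(r, name: str = "r"):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return r


def wca_energy(r, eps: float = 1.0):
    """Purely repulsive WCA energy at separation ``r`` (sigma units)."""
    r = _as_positive(r)
    inv6 = (1.0 / r) ** 6
    u = 4.0 * eps * (inv6 * inv6 - inv6 + 0.25)
    u = np.where(r <= WCA_CUTOFF, u, 0.0)
    return u if u.ndim else float(u)


def lj_attractive_energy(r, eps: float, rc: float = 1.8):
    """Truncated (unshifted) attractive LJ energy; minimum -eps at 2^(1/6)."""
    r = _as_positive(r)
    if rc <= WCA_CUTOFF:
        raise ValueError("attractive cutoff must exceed the WCA cutoff")
    inv6 = (1.0 / r) ** 6
    u = 4.0 * eps * (inv6 * inv6 - inv6)
    u = np.where(r <= rc, u, 0.0)
    return u if u.ndim else float(u)


def lj_force_over_r(r2, eps: float):
    """Radial LJ force magnitude divided by r, from the squared distance.

    ``F/r = 24 eps (2 r^-12 - r^-6) / r^2``; multiplying by the displacement
    vector gives the Cartesian force on bead i from bead j.  Valid for both
    the WCA and attractive branches (the energy shift has zero gradient).
    """
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    return 24.0 * eps * inv6 * (2.0 * inv6 - 1.0) * inv2


def fene_energy(r, k: float = 30.0, r0: float = 1.5):
    """FENE bond energy; diverges (raises) at the maximum extension r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be >= 0")
    if np.any(r >= r0):
        raise OverstretchError(f"FENE bond at or beyond maximum extension r0={r0}")
    x = (r / r0) ** 2
    u = -0.5 * k * r0 * r0 * np.log1p(-x)
    return u if u.ndim else float(u)


def bend_energy(t_a, t_b, k_bend: float = 3.0) -> float:
    """Bending energy k_bend (1 - cos alpha) between two bond tangents."""
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    na = np.linalg.norm(t_a)
    nb = np.linalg.norm(t_b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("tangent vectors must be non-zero")
    cos_a = float(np.dot(t_a, t_b) / (na * nb))
    cos_a = max(-1.0, min(1.0, cos_a))
    return k_bend * (1.0 - cos_a)


def minimum_image(d, box_side: float):
    """Map displacement components into (-box_side/2, box_side/2]."""
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    d = np.asarray(d, dtype=float)
    out = d - box_side * np.ceil(d / box_side - 0.5)
    return out if out.ndim else float(out)
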