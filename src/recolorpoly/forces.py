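"""Reference (numpy) energies and analytic forces.

This is the transparent O(N^2) implementation used for small systems, for
the finite-difference correctness tests, and as the independent cross-check
of the cell-list production kernels in :mod:`recolorpoly._kernels`.
"""

from __future__ import annotations

import numpy as np

from .params import SimulationParams
from .potentials import OverstretchError, lj_force_over_r, minimum_image
from .states import CHROMATIN
from .system import Configuration


def _pair_table(config: Configuration, params: SimulationParams, binding_on: bool):
    """Per-pair (eps, rc2) arrays for the non-bonded LJ/WCA interactions."""
    n = config.n_total
    nc = config.n_chromatin
    is_chrom = config.species == CHROMATIN
    marked = np.zeros(n, dtype=bool)
    ub = np.zeros(n, dtype=bool)
    marked[:nc] = (config.states & 1).astype(bool)
    ub[:nc] = (config.states & 2).astype(bool)

    eps = np.ones((n, n))
    rc2 = np.full((n, n), params.rc_wca**2)

    ub_pair = np.outer(ub, ub) & np.outer(is_chrom, is_chrom)
    eps[ub_pair] = params.eps_ub
    rc2[ub_pair] = params.rc_attr**2

    if binding_on:
        bind_pair = np.outer(~is_chrom, marked) | np.outer(marked, ~is_chrom)
        eps[bind_pair] = params.eps_bind
        rc2[bind_pair] = params.rc_attr**2
    return eps, rc2


def _pair_disp(config: Configuration):
    d = config.positions[None, :, :] - config.positions[:, None, :]
    return minimum_image(d, config.box_side)


def total_energy(
    config: Configuration, params: SimulationParams, binding_on: bool = True
) -> float:
    """Total potential energy (pair + FENE bonds + bending) in kBT."""
    n = config.n_total
    d = _pair_disp(config)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu = np.triu_indices(n, k=1)
    r2u = r2[iu]
    eps, rc2 = _pair_table(config, params, binding_on)
    epsu = eps[iu]
    rc2u = rc2[iu]
    inside = r2u < rc2u
    inv6 = 1.0 / r2u[inside] ** 3
    # WCA pairs carry the +eps/4 shift; attractive pairs are unshifted.
    shift = np.where(rc2u[inside] <= params.rc_wca**2 + 1e-12, 0.25, 0.0)
    e_pair = float(
        np.sum(4.0 * epsu[inside] * (inv6 * inv6 - inv6 + shift))
    )

    e_bond = 0.0
    nc = config.n_chromatin
    if nc > 1:
        bvec = minimum_image(
            np.diff(config.positions[:nc], axis=0), config.box_side
        )
        blen2 = np.einsum("ij,ij->i", bvec, bvec)
        x = blen2 / params.r0_fene**2
        if np.any(x >= 1.0):
            raise OverstretchError("FENE bond at or beyond maximum extension")
        e_bond = float(-0.5 * params.k_fene * params.r0_fene**2 * np.sum(np.log1p(-x)))

    e_bend = 0.0
    if nc > 2 and params.k_bend != 0.0:
        bvec = minimum_image(
            np.diff(config.positions[:nc], axis=0), config.box_side
        )
        blen = np.sqrt(np.einsum("ij,ij->i", bvec, bvec))
        t = bvec / blen[:, None]
        cos_a = np.einsum("ij,ij->i", t[:-1], t[1:])
        e_bend = float(params.k_bend * np.sum(1.0 - cos_a))

    return e_pair + e_bond + e_bend


def total_forces(
    config: Configuration, params: SimulationParams, binding_on: bool = True
) -> np.ndarray:
    """Analytic forces, -grad of :func:`total_energy`, in eps/sigma.

    Newton's third law holds pairwise by construction; a FENE bond at or
    beyond its maximum extension raises :class:`OverstretchError`.
    """
    n = config.n_total
    d = _pair_disp(config)  # d[i, j] = r_j - r_i (minimum image)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    eps, rc2 = _pair_table(config, params, binding_on)
    inside = r2 < rc2
    fr = np.zeros((n, n))
    fr[inside] = lj_force_over_r(r2[inside], eps[inside])
    # force on i from j is -fr * d[i, j] (repulsive when fr > 0)
    forces = -np.einsum("ij,ijk->ik", fr, d)

    nc = config.n_chromatin
    if nc > 1:
        bvec = minimum_image(np.diff(config.positions[:nc], axis=0), config.box_side)
        blen2 = np.einsum("ij,ij->i", bvec, bvec)
        x = blen2 / params.r0_fene**2
        if np.any(x >= 1.0):
            raise OverstretchError("FENE bond at or beyond maximum extension")
        # dU/dr / r = k / (1 - (r/r0)^2); force on bead i of bond (i, i+1)
        coef = params.k_fene / (1.0 - x)
        fbond = coef[:, None] * bvec
        forces[:nc - 1] += fbond
        forces[1:nc] -= fbond

    if nc > 2 and params.k_bend != 0.0:
        bvec = minimum_image(np.diff(config.positions[:nc], axis=0), config.box_side)
        blen = np.sqrt(np.einsum("ij,ij->i", bvec, bvec))
        for i in range(nc - 2):
            b1 = bvec[i]
            b2 = bvec[i + 1]
            n1 = blen[i]
            n2 = blen[i + 1]
            c = float(np.dot(b1, b2) / (n1 * n2))
            dc_db1 = b2 / (n1 * n2) - c * b1 / (n1 * n1)
            dc_db2 = b1 / (n1 * n2) - c * b2 / (n2 * n2)
            # U = k (1 - c); F_a = -dU/dr_a with b1 = r_{i+1}-r_i, b2 = r_{i+2}-r_{i+1}
            f_first = -params.k_bend * dc_db1
            f_last = params.k_bend * dc_db2
            forces[i] += f_first
            forces[i + 2] += f_last
            forces[i + 1] -= f_first + f_last
    return forces
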