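"""Numba kernels: cell-list neighbour search, forces, Langevin integration.

These are the production hot paths.  Their correctness is asserted against
the transparent numpy implementation in :mod:`recolorpoly.forces` and
against central finite differences in the test suite.

Layout notes: chromatin beads are indices ``0 .. n_chrom-1`` with an
epigenetic state byte (bit 0 = K27me3, bit 1 = Ub); higher indices are
proteins.  The Verlet list is built with a per-pair search radius — the
short WCA cutoff plus skin for purely repulsive pairs, the attraction
cutoff plus skin for reader-binding and Ub-Ub pairs — and stores the
resolved well depth and squared cutoff per pair, so the force loop is
branch-free.  Any change of the states, of the binding switch, or any
external position edit therefore requires a list rebuild (the integrator
handles this via ``npairs_io[0] = -1``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integrator
OK = 0
PAIR_OVERFLOW = -2


@njit(cache=True, inline="always")
def _min_image(d, box):
    if d > 0.5 * box:
        return d - box
    if d <= -0.5 * box:
        return d + box
    return d


@njit(cache=True, inline="always")
def _pair_params(i, j, states, n_chrom, binding_on, eps_bind, eps_ub,
                 rc_wca2, rc_attr2):
    """Resolve (eps, rc^2) for one pair from the species block and states."""
    i_chrom = i < n_chrom
    j_chrom = j < n_chrom
    if i_chrom and j_chrom:
        if (states[i] & 2) != 0 and (states[j] & 2) != 0:
            return eps_ub, rc_attr2
    elif i_chrom != j_chrom:
        if binding_on:
            k = i if i_chrom else j
            if (states[k] & 1) != 0:
                return eps_bind, rc_attr2
    return 1.0, rc_wca2


@njit(cache=True)
def build_pairs(pos, box, states, n_chrom, binding_on,
                eps_bind, eps_ub, rc_wca2, rc_attr2, skin,
                pair_i, pair_j, pair_eps, pair_rc2,
                head, nxt, occ):
    """Build the typed Verlet list with per-kind search radii.

    A pair enters the list when its squared distance is below
    ``(sqrt(rc2_pair) + skin)^2`` for its resolved interaction kind.
    ``head`` (cell heads, persistent scratch), ``nxt`` (per-bead chain) and
    ``occ`` (occupied-cell list) must be sized by the caller; ``head`` must
    arrive filled with -1 and is restored before returning.  Returns the
    pair count or PAIR_OVERFLOW.
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    rv_attr = np.sqrt(rc_attr2) + skin
    rv_wca = np.sqrt(rc_wca2) + skin
    rv_attr2 = rv_attr * rv_attr
    rv_wca2 = rv_wca * rv_wca
    ncell = int(box / rv_attr)
    npairs = 0

    if ncell < 3 or n < 48:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box)
                dy = _min_image(pos[i, 1] - pos[j, 1], box)
                dz = _min_image(pos[i, 2] - pos[j, 2], box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rv_attr2:
                    e, rc2 = _pair_params(i, j, states, n_chrom, binding_on,
                                          eps_bind, eps_ub, rc_wca2, rc_attr2)
                    if rc2 == rc_wca2 and r2 >= rv_wca2:
                        continue
                    if npairs >= cap:
                        return PAIR_OVERFLOW
                    pair_i[npairs] = i
                    pair_j[npairs] = j
                    pair_eps[npairs] = e
                    pair_rc2[npairs] = rc2
                    npairs += 1
        return npairs

    ntot = ncell * ncell * ncell
    if ntot > head.shape[0]:
        return PAIR_OVERFLOW
    inv_cell = ncell / box
    nocc = 0
    for i in range(n):
        ix = int(pos[i, 0] * inv_cell)
        iy = int(pos[i, 1] * inv_cell)
        iz = int(pos[i, 2] * inv_cell)
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        if iz >= ncell:
            iz = ncell - 1
        c = (ix * ncell + iy) * ncell + iz
        if head[c] < 0:
            occ[nocc] = c
            nocc += 1
        nxt[i] = head[c]
        head[c] = i

    # half stencil: the cell itself plus 13 forward neighbours
    status = 0
    for oc in range(nocc):
        c = occ[oc]
        iz = c % ncell
        iy = (c // ncell) % ncell
        ix = c // (ncell * ncell)
        for s in range(14):
            # offsets enumerated as (ox, oy, oz) with lexicographic ordering
            if s == 0:
                ox, oy, oz = 0, 0, 0
            elif s == 1:
                ox, oy, oz = 0, 0, 1
            elif s == 2:
                ox, oy, oz = 0, 1, -1
            elif s == 3:
                ox, oy, oz = 0, 1, 0
            elif s == 4:
                ox, oy, oz = 0, 1, 1
            elif s == 5:
                ox, oy, oz = 1, -1, -1
            elif s == 6:
                ox, oy, oz = 1, -1, 0
            elif s == 7:
                ox, oy, oz = 1, -1, 1
            elif s == 8:
                ox, oy, oz = 1, 0, -1
            elif s == 9:
                ox, oy, oz = 1, 0, 0
            elif s == 10:
                ox, oy, oz = 1, 0, 1
            elif s == 11:
                ox, oy, oz = 1, 1, -1
            elif s == 12:
                ox, oy, oz = 1, 1, 0
            else:
                ox, oy, oz = 1, 1, 1
            jx = ix + ox
            if jx >= ncell:
                jx -= ncell
            jy = iy + oy
            if jy >= ncell:
                jy -= ncell
            elif jy < 0:
                jy += ncell
            jz = iz + oz
            if jz >= ncell:
                jz -= ncell
            elif jz < 0:
                jz += ncell
            c2 = (jx * ncell + jy) * ncell + jz
            i = head[c]
            while i >= 0:
                j = head[c2] if s > 0 else nxt[i]
                while j >= 0:
                    dx = _min_image(pos[i, 0] - pos[j, 0], box)
                    dy = _min_image(pos[i, 1] - pos[j, 1], box)
                    dz = _min_image(pos[i, 2] - pos[j, 2], box)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rv_attr2:
                        e, rc2 = _pair_params(i, j, states, n_chrom,
                                              binding_on, eps_bind, eps_ub,
                                              rc_wca2, rc_attr2)
                        if not (rc2 == rc_wca2 and r2 >= rv_wca2):
                            if npairs >= cap:
                                status = PAIR_OVERFLOW
                            else:
                                pair_i[npairs] = i
                                pair_j[npairs] = j
                                pair_eps[npairs] = e
                                pair_rc2[npairs] = rc2
                                npairs += 1
                    j = nxt[j]
                i = nxt[i]
    # restore head to the all-empty state for the next build
    for oc in range(nocc):
        head[occ[oc]] = -1
    if status == PAIR_OVERFLOW:
        return PAIR_OVERFLOW
    return npairs


@njit(cache=True, fastmath=True)
def compute_forces(pos, box, pair_i, pair_j, pair_eps, pair_rc2, npairs,
                   n_chrom, k_fene, r0_fene, k_bend, bond_buf, forces):
    """Accumulate pair + FENE + bending forces into ``forces``.

    ``bond_buf`` is an (n_chrom-1, 4) scratch for bond vectors and squared
    lengths (reused by the bending loop).  Returns 0 on success, or
    (bond index + 1) on FENE overstretch.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    for p in range(npairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        fr = 24.0 * pair_eps[p] * inv6 * (2.0 * inv6 - 1.0) * inv2
        if r2 >= pair_rc2[p]:
            fr = 0.0
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    r02 = r0_fene * r0_fene
    for b in range(n_chrom - 1):
        dx = _min_image(pos[b + 1, 0] - pos[b, 0], box)
        dy = _min_image(pos[b + 1, 1] - pos[b, 1], box)
        dz = _min_image(pos[b + 1, 2] - pos[b, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        x = r2 / r02
        if x >= 1.0:
            return b + 1
        coef = k_fene / (1.0 - x)
        forces[b, 0] += coef * dx
        forces[b, 1] += coef * dy
        forces[b, 2] += coef * dz
        forces[b + 1, 0] -= coef * dx
        forces[b + 1, 1] -= coef * dy
        forces[b + 1, 2] -= coef * dz
        bond_buf[b, 0] = dx
        bond_buf[b, 1] = dy
        bond_buf[b, 2] = dz
        bond_buf[b, 3] = r2

    if k_bend != 0.0:
        for t in range(n_chrom - 2):
            b1x = bond_buf[t, 0]
            b1y = bond_buf[t, 1]
            b1z = bond_buf[t, 2]
            n1sq = bond_buf[t, 3]
            b2x = bond_buf[t + 1, 0]
            b2y = bond_buf[t + 1, 1]
            b2z = bond_buf[t + 1, 2]
            n2sq = bond_buf[t + 1, 3]
            inv12 = 1.0 / np.sqrt(n1sq * n2sq)
            c = (b1x * b2x + b1y * b2y + b1z * b2z) * inv12
            # F_first = -k dc/db1 ; F_last = +k dc/db2 ; middle balances
            f1x = -k_bend * (b2x * inv12 - c * b1x / n1sq)
            f1y = -k_bend * (b2y * inv12 - c * b1y / n1sq)
            f1z = -k_bend * (b2z * inv12 - c * b1z / n1sq)
            f3x = k_bend * (b1x * inv12 - c * b2x / n2sq)
            f3y = k_bend * (b1y * inv12 - c * b2y / n2sq)
            f3z = k_bend * (b1z * inv12 - c * b2z / n2sq)
            forces[t, 0] += f1x
            forces[t, 1] += f1y
            forces[t, 2] += f1z
            forces[t + 2, 0] += f3x
            forces[t + 2, 1] += f3y
            forces[t + 2, 2] += f3z
            forces[t + 1, 0] -= f1x + f3x
            forces[t + 1, 1] -= f1y + f3y
            forces[t + 1, 2] -= f1z + f3z
    return 0


@njit(cache=True, fastmath=True)
def run_chunk(pos, img, vel, states, n_chrom, box, nsteps, noise, dt, c1, c2,
              binding_on, eps_bind, eps_ub, rc_wca2, rc_attr2,
              k_fene, r0_fene, k_bend, skin, skin_half2,
              pair_i, pair_j, pair_eps, pair_rc2, head, nxt, occ,
              npairs_io, ref_pos, bond_buf, forces):
    """Advance ``nsteps`` BAOAB Langevin steps in place.

    ``noise`` is an (nsteps, n, 3) float32 array of standard normals from
    the caller's documented numpy stream.  ``npairs_io[0]`` carries the
    Verlet list length between calls, or -1 to force a rebuild.

    Returns OK, PAIR_OVERFLOW, or (bond index + 1) on FENE overstretch.
    """
    n = pos.shape[0]
    npairs = npairs_io[0]
    if npairs < 0:
        npairs = build_pairs(pos, box, states, n_chrom, binding_on,
                             eps_bind, eps_ub, rc_wca2, rc_attr2, skin,
                             pair_i, pair_j, pair_eps, pair_rc2,
                             head, nxt, occ)
        if npairs < 0:
            return PAIR_OVERFLOW
        for i in range(n):
            ref_pos[i, 0] = pos[i, 0]
            ref_pos[i, 1] = pos[i, 1]
            ref_pos[i, 2] = pos[i, 2]
    status = compute_forces(pos, box, pair_i, pair_j, pair_eps, pair_rc2,
                            npairs, n_chrom, k_fene, r0_fene, k_bend,
                            bond_buf, forces)
    if status != 0:
        npairs_io[0] = npairs
        return status

    half = 0.5 * dt
    for s in range(nsteps):
        max_d2 = 0.0
        for i in range(n):
            for d in range(3):
                v = vel[i, d] + half * forces[i, d]
                x = pos[i, d] + half * v
                v = c1 * v + c2 * noise[s, i, d]
                x = x + half * v
                if x >= box:
                    x -= box
                    img[i, d] += 1
                elif x < 0.0:
                    x += box
                    img[i, d] -= 1
                pos[i, d] = x
                vel[i, d] = v
            dx = _min_image(pos[i, 0] - ref_pos[i, 0], box)
            dy = _min_image(pos[i, 1] - ref_pos[i, 1], box)
            dz = _min_image(pos[i, 2] - ref_pos[i, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        # rebuild once any bead moved more than skin/2 since the last build
        if max_d2 > skin_half2:
            npairs = build_pairs(pos, box, states, n_chrom, binding_on,
                                 eps_bind, eps_ub, rc_wca2, rc_attr2, skin,
                                 pair_i, pair_j, pair_eps, pair_rc2,
                                 head, nxt, occ)
            if npairs < 0:
                npairs_io[0] = -1
                return PAIR_OVERFLOW
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]
                ref_pos[i, 2] = pos[i, 2]
        status = compute_forces(pos, box, pair_i, pair_j, pair_eps, pair_rc2,
                                npairs, n_chrom, k_fene, r0_fene, k_bend,
                                bond_buf, forces)
        if status != 0:
            npairs_io[0] = npairs
            return status
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
    npairs_io[0] = npairs
    return OK


@njit(cache=True, fastmath=True)
def local_density_counts(pos_chrom, box, radius):
    """Number of chromatin beads (self included) within ``radius`` of each."""
    n = pos_chrom.shape[0]
    r2 = radius * radius
    counts = np.ones(n, dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos_chrom[i, 0] - pos_chrom[j, 0], box)
            dy = _min_image(pos_chrom[i, 1] - pos_chrom[j, 1], box)
            dz = _min_image(pos_chrom[i, 2] - pos_chrom[j, 2], box)
            if dx * dx + dy * dy + dz * dz < r2:
                counts[i] += 1
                counts[j] += 1
    return counts
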