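"""Numba kernels for the kinetic Monte-Carlo dynamics.

Coordinates are kept *unfolded* (int64 grid units, spacing b/sqrt(2)), so
bond vectors are exact real-space vectors; folding happens only when
indexing the occupancy grid.  The occupancy grid stores up to two monomer
indices per folded site (double occupancy = stored length, consecutive
monomers only).

Energy convention: bending E(theta) = kappa * (1 - cos theta) per angle
formed by two consecutive *non-zero* bonds (a zero-length bond carries no
bending term and decorrelates the angle chain); epigenomic interaction
U[e(i), e(j)] for every unordered monomer pair |i - j| >= exclude_min
occupying nearest-neighbor folded sites.  Temperature is fixed at 1, all
energies in kT.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 12 nearest-neighbor offsets, duplicated here as a module constant so the
# kernels close over a plain array (keep in sync with lattice.NEIGHBOR_OFFSETS).
OFFSETS = np.array(
    [
        [1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
        [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
        [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1],
    ],
    dtype=np.int64,
)


@njit(cache=True, inline="always")
def _fold_index(x, y, z, M):
    return ((x % M) * M + (y % M)) * M + (z % M)


@njit(cache=True)
def build_occupancy(pos, M):
    """Occupancy grid from unfolded positions: count and two member slots."""
    n_sites = M * M * M
    occ_count = np.zeros(n_sites, dtype=np.int8)
    occ_a = np.full(n_sites, -1, dtype=np.int32)
    occ_b = np.full(n_sites, -1, dtype=np.int32)
    for m in range(pos.shape[0]):
        f = _fold_index(pos[m, 0], pos[m, 1], pos[m, 2], M)
        if occ_count[f] == 0:
            occ_a[f] = m
        elif occ_count[f] == 1:
            occ_b[f] = m
        occ_count[f] += 1
    return occ_count, occ_a, occ_b


@njit(cache=True, inline="always")
def _angle_term(pos, v, kappa):
    """Bending energy at vertex v (0 if either adjoining bond is zero)."""
    N = pos.shape[0]
    if v < 1 or v > N - 2:
        return 0.0
    ux = pos[v, 0] - pos[v - 1, 0]
    uy = pos[v, 1] - pos[v - 1, 1]
    uz = pos[v, 2] - pos[v - 1, 2]
    if ux == 0 and uy == 0 and uz == 0:
        return 0.0
    wx = pos[v + 1, 0] - pos[v, 0]
    wy = pos[v + 1, 1] - pos[v, 1]
    wz = pos[v + 1, 2] - pos[v, 2]
    if wx == 0 and wy == 0 and wz == 0:
        return 0.0
    dot = ux * wx + uy * wy + uz * wz  # |u| = |w| = sqrt(2) grid units
    return kappa * (1.0 - 0.5 * dot)


@njit(cache=True, inline="always")
def _pair_energy_at(m, x, y, z, M, occ_count, occ_a, occ_b, states, U, exclude_min):
    """Interaction energy of monomer m (state states[m]) if placed at (x,y,z)."""
    e = 0.0
    sm = states[m]
    for k in range(12):
        f = _fold_index(x + OFFSETS[k, 0], y + OFFSETS[k, 1], z + OFFSETS[k, 2], M)
        c = occ_count[f]
        if c > 0:
            j = occ_a[f]
            if j != m and abs(j - m) >= exclude_min:
                e += U[sm, states[j]]
            if c > 1:
                j = occ_b[f]
                if j != m and abs(j - m) >= exclude_min:
                    e += U[sm, states[j]]
    return e


@njit(cache=True)
def total_energy_kernel(pos, states, kappa, U, M, exclude_min):
    """Full Hamiltonian: bending + state-pair interactions (each pair once)."""
    N = pos.shape[0]
    e = 0.0
    for v in range(1, N - 1):
        e += _angle_term(pos, v, kappa)
    occ_count, occ_a, occ_b = build_occupancy(pos, M)
    for m in range(N):
        sm = states[m]
        for k in range(12):
            f = _fold_index(
                pos[m, 0] + OFFSETS[k, 0],
                pos[m, 1] + OFFSETS[k, 1],
                pos[m, 2] + OFFSETS[k, 2],
                M,
            )
            c = occ_count[f]
            if c > 0:
                j = occ_a[f]
                if j - m >= exclude_min:
                    e += U[sm, states[j]]
                if c > 1:
                    j = occ_b[f]
                    if j - m >= exclude_min:
                        e += U[sm, states[j]]
    return e


@njit(cache=True, inline="always")
def _occ_remove(f, m, occ_count, occ_a, occ_b):
    if occ_count[f] == 2:
        if occ_a[f] == m:
            occ_a[f] = occ_b[f]
        occ_b[f] = -1
        occ_count[f] = 1
    else:
        occ_a[f] = -1
        occ_count[f] = 0


@njit(cache=True, inline="always")
def _occ_add(f, m, occ_count, occ_a, occ_b):
    if occ_count[f] == 0:
        occ_a[f] = m
    else:
        occ_b[f] = m
    occ_count[f] += 1


@njit(cache=True)
def kmc_run(
    pos,
    states,
    kappa,
    U,
    M,
    n_mcs,
    snap_every,
    audit_every,
    seed,
    exclude_min,
    out_pos,
    out_mcs,
    out_energy,
    audit_out,
    has_interactions,
):
    """Run n_mcs Monte-Carlo steps (N trial moves each) of the KMC dynamics.

    Mutates ``pos`` in place.  Snapshots (unfolded positions, running
    energy) are written every ``snap_every`` MCS including the initial
    state; ``audit_out`` rows receive (mcs, incremental, recomputed) full
    energies every ``audit_every`` MCS (if > 0).  Returns (n_accepted,
    n_trials, final incremental energy).
    """
    np.random.seed(seed)
    N = pos.shape[0]
    occ_count, occ_a, occ_b = build_occupancy(pos, M)
    energy = total_energy_kernel(pos, states, kappa, U, M, exclude_min)

    snap_i = 0
    out_pos[snap_i] = pos
    out_mcs[snap_i] = 0
    out_energy[snap_i] = energy
    snap_i += 1
    audit_i = 0
    accepted = 0

    for mcs in range(1, n_mcs + 1):
        for _ in range(N):
            m = np.random.randint(0, N)
            k = np.random.randint(0, 12)
            nx = pos[m, 0] + OFFSETS[k, 0]
            ny = pos[m, 1] + OFFSETS[k, 1]
            nz = pos[m, 2] + OFFSETS[k, 2]

            # occupancy rule at the target site
            fn = _fold_index(nx, ny, nz, M)
            c = occ_count[fn]
            if c == 2:
                continue
            if c == 1:
                j = occ_a[fn]
                if abs(j - m) != 1:
                    continue

            # connectivity: both bonds must remain zero or nearest-neighbor
            ok = True
            if m > 0:
                dx = pos[m - 1, 0] - nx
                dy = pos[m - 1, 1] - ny
                dz = pos[m - 1, 2] - nz
                s = abs(dx) + abs(dy) + abs(dz)
                if not (s == 0 or (s == 2 and abs(dx) <= 1 and abs(dy) <= 1 and abs(dz) <= 1)):
                    ok = False
            if ok and m < N - 1:
                dx = pos[m + 1, 0] - nx
                dy = pos[m + 1, 1] - ny
                dz = pos[m + 1, 2] - nz
                s = abs(dx) + abs(dy) + abs(dz)
                if not (s == 0 or (s == 2 and abs(dx) <= 1 and abs(dy) <= 1 and abs(dz) <= 1)):
                    ok = False
            if not ok:
                continue

            # energy difference
            de = 0.0
            ox, oy, oz = pos[m, 0], pos[m, 1], pos[m, 2]
            fo = _fold_index(ox, oy, oz, M)
            e_old = _angle_term(pos, m - 1, kappa) + _angle_term(pos, m, kappa) + _angle_term(pos, m + 1, kappa)
            if has_interactions:
                e_old += _pair_energy_at(
                    m, ox, oy, oz, M, occ_count, occ_a, occ_b, states, U, exclude_min
                )
                _occ_remove(fo, m, occ_count, occ_a, occ_b)
            pos[m, 0], pos[m, 1], pos[m, 2] = nx, ny, nz
            e_new = _angle_term(pos, m - 1, kappa) + _angle_term(pos, m, kappa) + _angle_term(pos, m + 1, kappa)
            if has_interactions:
                e_new += _pair_energy_at(
                    m, nx, ny, nz, M, occ_count, occ_a, occ_b, states, U, exclude_min
                )
            de = e_new - e_old

            if de <= 0.0 or np.random.random() < np.exp(-de):
                if has_interactions:
                    _occ_add(fn, m, occ_count, occ_a, occ_b)
                else:
                    _occ_remove(fo, m, occ_count, occ_a, occ_b)
                    _occ_add(fn, m, occ_count, occ_a, occ_b)
                energy += de
                accepted += 1
            else:
                pos[m, 0], pos[m, 1], pos[m, 2] = ox, oy, oz
                if has_interactions:
                    _occ_add(fo, m, occ_count, occ_a, occ_b)

        if snap_every > 0 and mcs % snap_every == 0:
            out_pos[snap_i] = pos
            out_mcs[snap_i] = mcs
            out_energy[snap_i] = energy
            snap_i += 1
        if audit_every > 0 and mcs % audit_every == 0:
            ref = total_energy_kernel(pos, states, kappa, U, M, exclude_min)
            audit_out[audit_i, 0] = mcs
            audit_out[audit_i, 1] = energy
            audit_out[audit_i, 2] = ref
            audit_i += 1

    return accepted, n_mcs * N, energy
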