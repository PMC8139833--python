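"""Numba kernels for the Brownian-dynamics inner loop.

Layout and ordering here are deliberate: the half neighbor list is stored
per bead i with partners j > i sorted ascending, and all accumulations run
in (i, then j) order.  An all-pairs "neighbor list" therefore performs the
identical floating-point operations in the identical order, which makes
the cell-list path bit-for-bit reproducible against the quadratic
reference — the property the engine's equivalence tests rely on.

Energy term order everywhere: [stretch, bend, chrom_lj, wall, lamin_lj, bond].
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_ESCAPED = 2
STATUS_SINGULAR = 3

_MAX_CELLS_PER_DIM = 64

_zero_noise = np.zeros(1)


@njit(cache=True)
def _grid_geometry(lo, hi, rlist):
    # cells of ~rlist/2 with a 5^3 scan: the candidate volume is ~2x
    # tighter than single-rlist cells with a 3^3 scan
    ncell = np.empty(3, np.int64)
    csize = np.empty(3, np.float64)
    for d in range(3):
        span = hi[d] - lo[d]
        if span <= 0.0:
            span = 1e-9
        nc = int(2.0 * span / rlist)
        if nc < 1:
            nc = 1
        if nc > _MAX_CELLS_PER_DIM:
            nc = _MAX_CELLS_PER_DIM
        ncell[d] = nc
        csize[d] = span / nc
    return ncell, csize


@njit(cache=True)
def _assign_cells(pos, lo, ncell, csize):
    n = pos.shape[0]
    cell_of = np.empty(n, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - lo[0]) / csize[0])
        cy = int((pos[i, 1] - lo[1]) / csize[1])
        cz = int((pos[i, 2] - lo[2]) / csize[2])
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        if cx >= ncell[0]:
            cx = ncell[0] - 1
        if cy >= ncell[1]:
            cy = ncell[1] - 1
        if cz >= ncell[2]:
            cz = ncell[2] - 1
        cell_of[i] = (cx * ncell[1] + cy) * ncell[2] + cz
    return cell_of


@njit(cache=True)
def _linked_cells(cell_of, n_cells):
    head = np.full(n_cells, -1, np.int64)
    nxt = np.full(cell_of.shape[0], -1, np.int64)
    # Insert in reverse so traversal yields ascending indices.
    for i in range(cell_of.shape[0] - 1, -1, -1):
        nxt[i] = head[cell_of[i]]
        head[cell_of[i]] = i
    return head, nxt


@njit(cache=True)
def _bbox(pos):
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        mn = pos[0, d]
        mx = pos[0, d]
        for i in range(1, pos.shape[0]):
            v = pos[i, d]
            if v < mn:
                mn = v
            if v > mx:
                mx = v
        lo[d] = mn - 1e-9
        hi[d] = mx + 1e-9
    return lo, hi


@njit(cache=True)
def build_half_list(pos, rlist):
    """Half neighbor list (j > i), per-i slices sorted ascending, CSR layout."""
    n = pos.shape[0]
    lo, hi = _bbox(pos)
    ncell, csize = _grid_geometry(lo, hi, rlist)
    cell_of = _assign_cells(pos, lo, ncell, csize)
    head, nxt = _linked_cells(cell_of, ncell[0] * ncell[1] * ncell[2])
    r2 = rlist * rlist
    sx = int(rlist / csize[0]) + 1
    sy = int(rlist / csize[1]) + 1
    sz = int(rlist / csize[2]) + 1
    maxn = 256
    buf = np.empty((n, maxn), np.int64)
    cnt = np.zeros(n, np.int64)
    for i in range(n):
        ci = cell_of[i]
        cz = ci % ncell[2]
        cy = (ci // ncell[2]) % ncell[1]
        cx = ci // (ncell[1] * ncell[2])
        c = 0
        for dx in range(-sx, sx + 1):
            x = cx + dx
            if x < 0 or x >= ncell[0]:
                continue
            for dy in range(-sy, sy + 1):
                y = cy + dy
                if y < 0 or y >= ncell[1]:
                    continue
                for dz in range(-sz, sz + 1):
                    z = cz + dz
                    if z < 0 or z >= ncell[2]:
                        continue
                    j = head[(x * ncell[1] + y) * ncell[2] + z]
                    while j >= 0:
                        if j > i:
                            ddx = pos[i, 0] - pos[j, 0]
                            ddy = pos[i, 1] - pos[j, 1]
                            ddz = pos[i, 2] - pos[j, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz <= r2:
                                if c < maxn:
                                    buf[i, c] = j
                                c += 1
                        j = nxt[j]
        if c > maxn:
            c = maxn  # overflow beyond capacity is dropped; capacity is far
        cnt[i] = c       # above any physical neighbor count at these densities
        # insertion-sort the row so enumeration order is deterministic
        for p in range(1, c):
            key = buf[i, p]
            q = p - 1
            while q >= 0 and buf[i, q] > key:
                buf[i, q + 1] = buf[i, q]
                q -= 1
            buf[i, q + 1] = key
    counts = np.empty(n + 1, np.int64)
    counts[0] = 0
    for i in range(n):
        counts[i + 1] = counts[i] + cnt[i]
    idx = np.empty(counts[n], np.int64)
    for i in range(n):
        a = counts[i]
        for p in range(cnt[i]):
            idx[a + p] = buf[i, p]
    return counts, idx


@njit(cache=True)
def build_all_half_list(n):
    counts = np.empty(n + 1, np.int64)
    counts[0] = 0
    for i in range(n):
        counts[i + 1] = counts[i] + (n - 1 - i)
    idx = np.empty(counts[n], np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            idx[k] = j
            k += 1
    return counts, idx


@njit(cache=True)
def build_cross_list(pos, lam, rlist, r_conf):
    """For each chromatin bead, lamin beads within rlist; slices sorted ascending.

    Beads deeper than ``rlist`` below the confinement radius cannot have
    lamin neighbors (lamin beads sit exactly on the sphere) and are
    skipped without a cell scan.
    """
    n = pos.shape[0]
    lo, hi = _bbox(lam)
    ncell, csize = _grid_geometry(lo, hi, rlist)
    cell_of = _assign_cells(lam, lo, ncell, csize)
    head, nxt = _linked_cells(cell_of, ncell[0] * ncell[1] * ncell[2])
    r2 = rlist * rlist
    sx = int(rlist / csize[0]) + 1
    sy = int(rlist / csize[1]) + 1
    sz = int(rlist / csize[2]) + 1
    rmin2 = (r_conf - rlist) * (r_conf - rlist)
    maxn = 256
    buf = np.empty((n, maxn), np.int64)
    cnt = np.zeros(n, np.int64)
    for i in range(n):
        rad2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
        if r_conf > rlist and rad2 < rmin2:
            cnt[i] = 0
            continue
        cx = int((pos[i, 0] - lo[0]) / csize[0])
        cy = int((pos[i, 1] - lo[1]) / csize[1])
        cz = int((pos[i, 2] - lo[2]) / csize[2])
        c = 0
        for dx in range(-sx, sx + 1):
            x = cx + dx
            if x < 0 or x >= ncell[0]:
                continue
            for dy in range(-sy, sy + 1):
                y = cy + dy
                if y < 0 or y >= ncell[1]:
                    continue
                for dz in range(-sz, sz + 1):
                    z = cz + dz
                    if z < 0 or z >= ncell[2]:
                        continue
                    j = head[(x * ncell[1] + y) * ncell[2] + z]
                    while j >= 0:
                        ddx = pos[i, 0] - lam[j, 0]
                        ddy = pos[i, 1] - lam[j, 1]
                        ddz = pos[i, 2] - lam[j, 2]
                        if ddx * ddx + ddy * ddy + ddz * ddz <= r2:
                            if c < maxn:
                                buf[i, c] = j
                            c += 1
                        j = nxt[j]
        if c > maxn:
            c = maxn
        cnt[i] = c
        for p in range(1, c):
            key = buf[i, p]
            q = p - 1
            while q >= 0 and buf[i, q] > key:
                buf[i, q + 1] = buf[i, q]
                q -= 1
            buf[i, q + 1] = key
    counts = np.empty(n + 1, np.int64)
    counts[0] = 0
    for i in range(n):
        counts[i + 1] = counts[i] + cnt[i]
    idx = np.empty(counts[n], np.int64)
    for i in range(n):
        a = counts[i]
        for p in range(cnt[i]):
            idx[a + p] = buf[i, p]
    return counts, idx


@njit(cache=True)
def build_all_cross_list(n, m):
    counts = np.empty(n + 1, np.int64)
    for i in range(n + 1):
        counts[i] = i * m
    idx = np.empty(n * m, np.int64)
    k = 0
    for i in range(n):
        for j in range(m):
            idx[k] = j
            k += 1
    return counts, idx


@njit(cache=True)
def compute_forces(
    pos,
    types,
    partner,
    lam,
    cc_counts,
    cc_idx,
    cl_counts,
    cl_idx,
    rc_conf,
    sigma,
    ks,
    rest,
    kb,
    eps_mat,
    rc_cc,
    eps_lm,
    rc_lm,
    eps_ln,
    rc_ln,
    eps_wall,
    rc_wall,
    kbond,
    rbond,
    forces,
    energy,
    want_energy,
):
    """Fill ``forces`` (N,3) and ``energy`` (6,); return a status code.

    Energy accumulation is skipped when ``want_energy`` is false (the
    integrator only needs energies at sample steps)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for t in range(6):
        energy[t] = 0.0

    # stretching springs
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return STATUS_SINGULAR
        if want_energy:
            energy[0] += ks * (r - rest) * (r - rest)
        fmag = 2.0 * ks * (r - rest) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[i + 1, 0] -= fmag * dx
        forces[i + 1, 1] -= fmag * dy
        forces[i + 1, 2] -= fmag * dz

    # bending
    if kb != 0.0:
        for i in range(1, n - 1):
            b1x = pos[i, 0] - pos[i - 1, 0]
            b1y = pos[i, 1] - pos[i - 1, 1]
            b1z = pos[i, 2] - pos[i - 1, 2]
            b2x = pos[i + 1, 0] - pos[i, 0]
            b2y = pos[i + 1, 1] - pos[i, 1]
            b2z = pos[i + 1, 2] - pos[i, 2]
            n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if n1 < 1e-12 or n2 < 1e-12:
                return STATUS_SINGULAR
            dot = b1x * b2x + b1y * b2y + b1z * b2z
            c = dot / (n1 * n2)
            if want_energy:
                energy[1] += kb * (1.0 - c)
            inv12 = 1.0 / (n1 * n2)
            g1x = b2x * inv12 - c * b1x / (n1 * n1)
            g1y = b2y * inv12 - c * b1y / (n1 * n1)
            g1z = b2z * inv12 - c * b1z / (n1 * n1)
            g2x = b1x * inv12 - c * b2x / (n2 * n2)
            g2y = b1y * inv12 - c * b2y / (n2 * n2)
            g2z = b1z * inv12 - c * b2z / (n2 * n2)
            forces[i - 1, 0] -= kb * g1x
            forces[i - 1, 1] -= kb * g1y
            forces[i - 1, 2] -= kb * g1z
            forces[i, 0] += kb * (g1x - g2x)
            forces[i, 1] += kb * (g1y - g2y)
            forces[i, 2] += kb * (g1z - g2z)
            forces[i + 1, 0] += kb * g2x
            forces[i + 1, 1] += kb * g2y
            forces[i + 1, 2] += kb * g2z

    # chromatin-chromatin LJ (truncated-shifted energy, unshifted force)
    rc2 = rc_cc * rc_cc
    sr6c = (sigma / rc_cc) ** 6
    cshift = 4.0 * (sr6c * sr6c - sr6c)
    for i in range(n):
        a, b = cc_counts[i], cc_counts[i + 1]
        for p in range(a, b):
            j = cc_idx[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                if r2 < 1e-20:
                    return STATUS_SINGULAR
                eps = eps_mat[types[i], types[j]]
                inv = 1.0 / r2
                sr2 = (sigma * sigma) * inv
                sr6 = sr2 * sr2 * sr2
                if want_energy:
                    energy[2] += 4.0 * eps * (sr6 * sr6 - sr6) - eps * cshift
                fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz

    if rc_conf > 0.0:
        # continuum wall on the gap g = R_c - |r|
        rw2 = rc_wall
        sr6w_c = (sigma / rc_wall) ** 6
        wshift = 4.0 * (sr6w_c * sr6w_c - sr6w_c)
        for i in range(n):
            rad2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
            rad = np.sqrt(rad2)
            g = rc_conf - rad
            if g <= 0.0:
                return STATUS_ESCAPED
            if g < rw2:
                invg2 = (sigma * sigma) / (g * g)
                sr6 = invg2 * invg2 * invg2
                if want_energy:
                    energy[3] += 4.0 * eps_wall * (sr6 * sr6 - sr6) - eps_wall * wshift
                if rad > 1e-12:
                    fmag = 24.0 * eps_wall * (2.0 * sr6 * sr6 - sr6) / g
                    forces[i, 0] -= fmag * pos[i, 0] / rad
                    forces[i, 1] -= fmag * pos[i, 1] / rad
                    forces[i, 2] -= fmag * pos[i, 2] / rad

        # lamin-bead LJ: attractive for LAD, WCA for non-LAD
        sr6m = (sigma / rc_lm) ** 6
        mshift = 4.0 * (sr6m * sr6m - sr6m)
        sr6n = (sigma / rc_ln) ** 6
        nshift = 4.0 * (sr6n * sr6n - sr6n)
        rc_lm2 = rc_lm * rc_lm
        rc_ln2 = rc_ln * rc_ln
        for i in range(n):
            if types[i] == 1:
                eps_l = eps_lm
                rcl2 = rc_lm2
                shift = mshift
            else:
                eps_l = eps_ln
                rcl2 = rc_ln2
                shift = nshift
            a, b = cl_counts[i], cl_counts[i + 1]
            for p in range(a, b):
                j = cl_idx[p]
                dx = pos[i, 0] - lam[j, 0]
                dy = pos[i, 1] - lam[j, 1]
                dz = pos[i, 2] - lam[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rcl2:
                    if r2 < 1e-20:
                        return STATUS_SINGULAR
                    inv = 1.0 / r2
                    sr2 = (sigma * sigma) * inv
                    sr6 = sr2 * sr2 * sr2
                    if want_energy:
                        energy[4] += 4.0 * eps_l * (sr6 * sr6 - sr6) - eps_l * shift
                    fr = 24.0 * eps_l * (2.0 * sr6 * sr6 - sr6) * inv
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[i, 2] += fr * dz

        # LAD-lamina bond springs
        for i in range(n):
            j = partner[i]
            if j >= 0:
                dx = pos[i, 0] - lam[j, 0]
                dy = pos[i, 1] - lam[j, 1]
                dz = pos[i, 2] - lam[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if want_energy:
                    energy[5] += -kbond * (rbond - sigma) ** 2 + kbond * (r - sigma) ** 2
                if r > 1e-12:
                    fmag = 2.0 * kbond * (r - sigma) / r
                    forces[i, 0] -= fmag * dx
                    forces[i, 1] -= fmag * dy
                    forces[i, 2] -= fmag * dz
    return STATUS_OK


@njit(cache=True)
def seed_rng(seed):
    """Seed the kernel-side RNG (used by tests that call bond updates directly)."""
    np.random.seed(seed)


@njit(cache=True)
def _update_bonds_kernel(pos, bondable, partner, lam, cl_counts, cl_idx, rbond, p_break):
    n = pos.shape[0]
    rb2 = rbond * rbond
    # breaking pass: only bonds stretched beyond rbond may break
    for i in range(n):
        j = partner[i]
        if j >= 0:
            dx = pos[i, 0] - lam[j, 0]
            dy = pos[i, 1] - lam[j, 1]
            dz = pos[i, 2] - lam[j, 2]
            if dx * dx + dy * dy + dz * dz > rb2:
                if np.random.random() < p_break:
                    partner[i] = -1
    # formation pass: nearest lamin bead within rbond, lowest index on ties
    for i in range(n):
        if bondable[i] and partner[i] < 0:
            best = -1
            bestd2 = rb2
            a, b = cl_counts[i], cl_counts[i + 1]
            for p in range(a, b):
                j = cl_idx[p]
                dx = pos[i, 0] - lam[j, 0]
                dy = pos[i, 1] - lam[j, 1]
                dz = pos[i, 2] - lam[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < bestd2:
                    bestd2 = d2
                    best = j
            if best >= 0:
                partner[i] = best


@njit(cache=True)
def run_chunk(
    pos,
    types,
    bondable,
    partner,
    lam,
    rc_conf,
    sigma,
    ks,
    rest,
    kb,
    eps_mat,
    rc_cc,
    eps_lm,
    rc_lm,
    eps_ln,
    rc_ln,
    eps_wall,
    rc_wall,
    kbond,
    rbond,
    p_break,
    bonds_active,
    dt_mob,
    noise_amp,
    noise_uniform,
    noise_off,
    cap_disp,
    skin,
    use_all_pairs,
    n_steps,
    sample_every,
    store_frames,
    seed,
    frames,
    rg_out,
    en_out,
    bc_out,
    partners_out,
    fail_bead,
):
    """Advance ``n_steps`` overdamped Langevin steps in place.

    Returns ``(status, step)`` where step is the failing step for error
    statuses.  Samples (R_g, energy breakdown, bond count, optional frame)
    are recorded after every ``sample_every``-th step, post-move and
    post-bond-update.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    m = lam.shape[0]
    rlist_cc = rc_cc + skin
    rl = rc_lm
    if rbond > rl:
        rl = rbond
    if rc_ln > rl:
        rl = rc_ln
    rlist_cl = rl + skin

    if use_all_pairs:
        cc_counts, cc_idx = build_all_half_list(n)
        if m > 0:
            cl_counts, cl_idx = build_all_cross_list(n, m)
        else:
            cl_counts = np.zeros(n + 1, np.int64)
            cl_idx = np.empty(0, np.int64)
    else:
        cc_counts, cc_idx = build_half_list(pos, rlist_cc)
        if m > 0:
            cl_counts, cl_idx = build_cross_list(pos, lam, rlist_cl, rc_conf)
        else:
            cl_counts = np.zeros(n + 1, np.int64)
            cl_idx = np.empty(0, np.int64)

    ref_pos = pos.copy()
    forces = np.empty((n, 3))
    energy = np.empty(6)
    half_skin2 = 0.25 * skin * skin
    max_disp2 = 0.25 * sigma * sigma
    sample_i = 0

    for step in range(n_steps):
        if not use_all_pairs:
            moved = 0.0
            for i in range(n):
                dx = pos[i, 0] - ref_pos[i, 0]
                dy = pos[i, 1] - ref_pos[i, 1]
                dz = pos[i, 2] - ref_pos[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > moved:
                    moved = d2
            if moved > half_skin2:
                cc_counts, cc_idx = build_half_list(pos, rlist_cc)
                if m > 0:
                    cl_counts, cl_idx = build_cross_list(pos, lam, rlist_cl, rc_conf)
                for i in range(n):
                    ref_pos[i, 0] = pos[i, 0]
                    ref_pos[i, 1] = pos[i, 1]
                    ref_pos[i, 2] = pos[i, 2]

        status = compute_forces(
            pos, types, partner, lam, cc_counts, cc_idx, cl_counts, cl_idx,
            rc_conf, sigma, ks, rest, kb, eps_mat, rc_cc,
            eps_lm, rc_lm, eps_ln, rc_ln, eps_wall, rc_wall,
            kbond, rbond, forces, energy, False,
        )
        if status != STATUS_OK:
            return status, step

        if not noise_off:
            if noise_uniform:
                xi = 2.0 * np.random.random(3 * n) - 1.0
            else:
                xi = np.random.standard_normal(3 * n)
        else:
            xi = _zero_noise
        for i in range(n):
            ddx = dt_mob * forces[i, 0]
            ddy = dt_mob * forces[i, 1]
            ddz = dt_mob * forces[i, 2]
            # guard on the deterministic drift: a drift above sigma/2 in
            # one step signals a force blow-up (thermal noise alone may
            # legitimately exceed it at large dt)
            drift2 = ddx * ddx + ddy * ddy + ddz * ddz
            if cap_disp <= 0.0 and drift2 > max_disp2:
                fail_bead[0] = i
                return STATUS_UNSTABLE, step
            if not noise_off:
                ddx += noise_amp * xi[3 * i]
                ddy += noise_amp * xi[3 * i + 1]
                ddz += noise_amp * xi[3 * i + 2]
            if cap_disp > 0.0:
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > cap_disp * cap_disp:
                    scale = cap_disp / np.sqrt(d2)
                    ddx *= scale
                    ddy *= scale
                    ddz *= scale
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz

        if bonds_active and m > 0:
            _update_bonds_kernel(pos, bondable, partner, lam, cl_counts, cl_idx, rbond, p_break)

        if sample_every > 0 and (step + 1) % sample_every == 0:
            status = compute_forces(
                pos, types, partner, lam, cc_counts, cc_idx, cl_counts, cl_idx,
                rc_conf, sigma, ks, rest, kb, eps_mat, rc_cc,
                eps_lm, rc_lm, eps_ln, rc_ln, eps_wall, rc_wall,
                kbond, rbond, forces, energy, True,
            )
            if status != STATUS_OK:
                return status, step
            cmx = 0.0
            cmy = 0.0
            cmz = 0.0
            for i in range(n):
                cmx += pos[i, 0]
                cmy += pos[i, 1]
                cmz += pos[i, 2]
            cmx /= n
            cmy /= n
            cmz /= n
            rg2 = 0.0
            for i in range(n):
                rg2 += (pos[i, 0] - cmx) ** 2 + (pos[i, 1] - cmy) ** 2 + (pos[i, 2] - cmz) ** 2
            rg_out[sample_i] = np.sqrt(rg2 / n)
            for t in range(6):
                en_out[sample_i, t] = energy[t]
            bc = 0
            for i in range(n):
                if partner[i] >= 0:
                    bc += 1
            bc_out[sample_i] = bc
            if store_frames:
                for i in range(n):
                    frames[sample_i, i, 0] = pos[i, 0]
                    frames[sample_i, i, 1] = pos[i, 1]
                    frames[sample_i, i, 2] = pos[i, 2]
                    partners_out[sample_i, i] = partner[i]
            sample_i += 1

    return STATUS_OK, n_steps
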