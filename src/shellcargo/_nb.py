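"""Numba kernels shared by the interaction, dynamics and thermodynamics code.

All kernels operate on flat numpy arrays.  Pair interactions are dispatched
through per-type-pair parameter tables (see interactions.PairTables):

* ``kind``  : 0 none, 1 Morse, 2 WCA (purely repulsive LJ), 3 cut-shifted LJ
* ``eps``   : well depth / repulsion strength (k_B T)
* ``par``   : Morse inverse range alpha, or LJ/WCA sigma
* ``req``   : Morse rest length (unused otherwise)
* ``rcut2`` : squared cutoff
* ``shift`` : energy shift subtracted so the potential vanishes at the cutoff
"""

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z)
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def quat_to_mat(q, m):
    w, x, y, z = q[0], q[1], q[2], q[3]
    m[0, 0] = 1 - 2 * (y * y + z * z)
    m[0, 1] = 2 * (x * y - w * z)
    m[0, 2] = 2 * (x * z + w * y)
    m[1, 0] = 2 * (x * y + w * z)
    m[1, 1] = 1 - 2 * (x * x + z * z)
    m[1, 2] = 2 * (y * z - w * x)
    m[2, 0] = 2 * (x * z - w * y)
    m[2, 1] = 2 * (y * z + w * x)
    m[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True, inline="always")
def quat_mul(a, b, out):
    aw, ax, ay, az = a[0], a[1], a[2], a[3]
    bw, bx, by, bz = b[0], b[1], b[2], b[3]
    out[0] = aw * bw - ax * bx - ay * by - az * bz
    out[1] = aw * bx + ax * bw + ay * bz - az * by
    out[2] = aw * by - ax * bz + ay * bw + az * bx
    out[3] = aw * bz + ax * by - ay * bx + az * bw


@njit(cache=True)
def fill_site_positions(pos, rel, bod, body_pos, body_quat, cargo_pos):
    n = pos.shape[0]
    m = np.empty((3, 3))
    b_prev = -2
    for s in range(n):
        b = bod[s]
        if b < 0:
            c = s - (n - cargo_pos.shape[0])
            pos[s, 0] = cargo_pos[c, 0]
            pos[s, 1] = cargo_pos[c, 1]
            pos[s, 2] = cargo_pos[c, 2]
        else:
            if b != b_prev:
                quat_to_mat(body_quat[b], m)
                b_prev = b
            for k in range(3):
                pos[s, k] = (body_pos[b, k] + m[k, 0] * rel[s, 0]
                             + m[k, 1] * rel[s, 1] + m[k, 2] * rel[s, 2])


# ---------------------------------------------------------------------------
# pair potential dispatch
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def pair_ef(kind, eps, par, req, rcut2, shift, r2):
    """Energy and force/r for one site pair at squared distance r2."""
    if kind == 0 or r2 >= rcut2:
        return 0.0, 0.0
    if kind == 1:  # Morse
        r = np.sqrt(r2)
        x = np.exp(-par * (r - req))
        e = eps * ((1.0 - x) * (1.0 - x) - 1.0) - shift
        dvdr = 2.0 * eps * par * x * (1.0 - x)
        if r > 1e-9:
            return e, -dvdr / r
        return e, -2.0 * eps * par * par
    # WCA / LJ
    s2 = par * par / r2
    s6 = s2 * s2 * s2
    if kind == 2:  # WCA: shift = -eps (added), cutoff at 2^(1/6) sigma
        e = 4.0 * eps * (s6 * s6 - s6) + eps
    else:
        e = 4.0 * eps * (s6 * s6 - s6) - shift
    fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
    return e, fr


@njit(cache=True, inline="always")
def _min_image(d, box):
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


# ---------------------------------------------------------------------------
# brute-force all-pairs energy/forces (reference path)
# ---------------------------------------------------------------------------
@njit(cache=True)
def ef_brute(pos, typ, bod, box, kind, eps, par, req, rcut2, shift):
    n = pos.shape[0]
    F = np.zeros((n, 3))
    E = 0.0
    for i in range(n):
        ti = typ[i]
        for j in range(i + 1, n):
            if bod[i] >= 0 and bod[i] == bod[j]:
                continue
            tj = typ[j]
            if kind[ti, tj] == 0:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box)
            dy = _min_image(pos[i, 1] - pos[j, 1], box)
            dz = _min_image(pos[i, 2] - pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            e, fr = pair_ef(kind[ti, tj], eps[ti, tj], par[ti, tj],
                            req[ti, tj], rcut2[ti, tj], shift[ti, tj], r2)
            if e != 0.0 or fr != 0.0:
                E += e
                F[i, 0] += fr * dx
                F[i, 1] += fr * dy
                F[i, 2] += fr * dz
                F[j, 0] -= fr * dx
                F[j, 1] -= fr * dy
                F[j, 2] -= fr * dz
    return E, F


# ---------------------------------------------------------------------------
# cell-list Verlet pair construction
# ---------------------------------------------------------------------------
@njit(cache=True)
def build_pairs(pos, typ, bod, box, kind, rcut2, skin, max_rcut):
    """Half list of candidate interacting site pairs within rcut_ij + skin."""
    n = pos.shape[0]
    cell = max_rcut + skin
    nc = int(box / cell)
    if nc < 3:
        # fall back: all interacting pairs
        cnt = 0
        for i in range(n):
            for j in range(i + 1, n):
                if bod[i] >= 0 and bod[i] == bod[j]:
                    continue
                if kind[typ[i], typ[j]] != 0:
                    cnt += 1
        pairs = np.empty((cnt, 2), dtype=np.int32)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if bod[i] >= 0 and bod[i] == bod[j]:
                    continue
                if kind[typ[i], typ[j]] != 0:
                    pairs[k, 0] = i
                    pairs[k, 1] = j
                    k += 1
        return pairs
    lc = box / nc
    ncell = nc * nc * nc
    # assign cells
    ci = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] % box
        y = pos[i, 1] % box
        z = pos[i, 2] % box
        a = min(int(x / lc), nc - 1)
        b = min(int(y / lc), nc - 1)
        c = min(int(z / lc), nc - 1)
        ci[i] = (a * nc + b) * nc + c
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        count[ci[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        order[fill[ci[i]]] = i
        fill[ci[i]] += 1

    # neighbor cell offsets: half-space enumeration (13 neighbors + self)
    offs = np.empty((13, 3), dtype=np.int64)
    k = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx * 9 + dy * 3 + dz > 0:
                    offs[k, 0] = dx
                    offs[k, 1] = dy
                    offs[k, 2] = dz
                    k += 1

    pairs = np.empty((0, 2), dtype=np.int32)
    for ipass in range(2):
        cnt = 0
        for a in range(nc):
            for b in range(nc):
                for c in range(nc):
                    c0 = (a * nc + b) * nc + c
                    # within-cell pairs
                    for ii in range(count[c0], count[c0 + 1]):
                        i = order[ii]
                        for jj in range(ii + 1, count[c0 + 1]):
                            j = order[jj]
                            cnt = _try_pair(pos, typ, bod, box, kind, rcut2,
                                            skin, i, j, cnt, ipass, pairs)
                    # neighbor-cell pairs
                    for o in range(13):
                        a2 = (a + offs[o, 0]) % nc
                        b2 = (b + offs[o, 1]) % nc
                        c2 = (c + offs[o, 2]) % nc
                        c1 = (a2 * nc + b2) * nc + c2
                        for ii in range(count[c0], count[c0 + 1]):
                            i = order[ii]
                            for jj in range(count[c1], count[c1 + 1]):
                                j = order[jj]
                                cnt = _try_pair(pos, typ, bod, box, kind,
                                                rcut2, skin, i, j, cnt, ipass,
                                                pairs)
        if ipass == 0:
            pairs = np.empty((cnt, 2), dtype=np.int32)
    return pairs


@njit(cache=True, inline="always")
def _try_pair(pos, typ, bod, box, kind, rcut2, skin, i, j, cnt, ipass, pairs):
    if bod[i] >= 0 and bod[i] == bod[j]:
        return cnt
    ti = typ[i]
    tj = typ[j]
    if kind[ti, tj] == 0:
        return cnt
    dx = _min_image(pos[i, 0] - pos[j, 0], box)
    dy = _min_image(pos[i, 1] - pos[j, 1], box)
    dz = _min_image(pos[i, 2] - pos[j, 2], box)
    r2 = dx * dx + dy * dy + dz * dz
    rc = np.sqrt(rcut2[ti, tj]) + skin
    if r2 < rc * rc:
        if ipass == 1:
            pairs[cnt, 0] = i
            pairs[cnt, 1] = j
        cnt += 1
    return cnt


@njit(cache=True)
def ef_pairs(pos, typ, bod, box, pairs, kind, eps, par, req, rcut2, shift, F):
    E = 0.0
    F[:] = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        ti = typ[i]
        tj = typ[j]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        e, fr = pair_ef(kind[ti, tj], eps[ti, tj], par[ti, tj], req[ti, tj],
                        rcut2[ti, tj], shift[ti, tj], r2)
        if e != 0.0 or fr != 0.0:
            E += e
            F[i, 0] += fr * dx
            F[i, 1] += fr * dy
            F[i, 2] += fr * dz
            F[j, 0] -= fr * dx
            F[j, 1] -= fr * dy
            F[j, 2] -= fr * dz
    return E


@njit(cache=True)
def reduce_body_forces(site_F, site_pos, site_bod, body_pos, body_F, body_T,
                       cargo_F):
    """Sum site forces into per-body force and lab-frame torque about each
    body center, and copy cargo site forces.  Site positions are stored
    unwrapped relative to their body center, so torque arms are exact."""
    body_F[:] = 0.0
    body_T[:] = 0.0
    n = site_F.shape[0]
    ncargo = cargo_F.shape[0]
    for s in range(n):
        b = site_bod[s]
        if b < 0:
            c = s - (n - ncargo)
            cargo_F[c, 0] = site_F[s, 0]
            cargo_F[c, 1] = site_F[s, 1]
            cargo_F[c, 2] = site_F[s, 2]
        else:
            fx, fy, fz = site_F[s, 0], site_F[s, 1], site_F[s, 2]
            body_F[b, 0] += fx
            body_F[b, 1] += fy
            body_F[b, 2] += fz
            ax = site_pos[s, 0] - body_pos[b, 0]
            ay = site_pos[s, 1] - body_pos[b, 1]
            az = site_pos[s, 2] - body_pos[b, 2]
            body_T[b, 0] += ay * fz - az * fy
            body_T[b, 1] += az * fx - ax * fz
            body_T[b, 2] += ax * fy - ay * fx


# ---------------------------------------------------------------------------
# fast split-grid pair machinery for the integrator
#
# Two grids: grid A holds subunit pseudoatoms that interact with other
# subunit pseudoatoms (attractors + Top/Bottom); grid B holds cargo plus the
# subunit sites that interact with cargo (Excluders + axial Bottoms).  Grid B
# only stores pairs involving at least one cargo site, so subunit-subunit
# pairs are never double counted.  Pair parameters are linearized at build
# time so the per-step force loop reads flat arrays.
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _grid_fill(pos, typ, bod, bodfix, box, kind, rcutb2, eps, par, req, rcut2,
               shift, idx, cell_size, need_cargo, pi, pj, pk, pe, pp, pq, pr2,
               ps, cnt):
    n = idx.shape[0]
    if n == 0:
        return cnt
    cap = pi.shape[0]
    nc = int(box / cell_size)
    if nc < 3:
        for ii in range(n):
            i = idx[ii]
            for jj in range(ii + 1, n):
                j = idx[jj]
                bi = bod[i]
                bj = bod[j]
                if bi >= 0 and bi == bj:
                    continue
                if need_cargo and bi >= 0 and bj >= 0:
                    continue
                if bi >= 0 and bj >= 0 and bodfix[bi] == 1 and bodfix[bj] == 1:
                    continue
                ti = typ[i]
                tj = typ[j]
                if kind[ti, tj] == 0:
                    continue
                dx = _min_image(pos[i, 0] - pos[j, 0], box)
                dy = _min_image(pos[i, 1] - pos[j, 1], box)
                dz = _min_image(pos[i, 2] - pos[j, 2], box)
                if dx * dx + dy * dy + dz * dz < rcutb2[ti, tj]:
                    if cnt >= cap:
                        return -1
                    pi[cnt] = i
                    pj[cnt] = j
                    pk[cnt] = kind[ti, tj]
                    pe[cnt] = eps[ti, tj]
                    pp[cnt] = par[ti, tj]
                    pq[cnt] = req[ti, tj]
                    pr2[cnt] = rcut2[ti, tj]
                    ps[cnt] = shift[ti, tj]
                    cnt += 1
        return cnt
    lc = box / nc
    ncell = nc * nc * nc
    ci = np.empty(n, dtype=np.int64)
    for ii in range(n):
        i = idx[ii]
        a = min(int((pos[i, 0] % box) / lc), nc - 1)
        b = min(int((pos[i, 1] % box) / lc), nc - 1)
        c = min(int((pos[i, 2] % box) / lc), nc - 1)
        ci[ii] = (a * nc + b) * nc + c
    count = np.zeros(ncell + 1, dtype=np.int64)
    for ii in range(n):
        count[ci[ii] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for ii in range(n):
        order[fill[ci[ii]]] = idx[ii]
        fill[ci[ii]] += 1

    offs = np.empty((13, 3), dtype=np.int64)
    k = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx * 9 + dy * 3 + dz > 0:
                    offs[k, 0] = dx
                    offs[k, 1] = dy
                    offs[k, 2] = dz
                    k += 1

    for a in range(nc):
        for b in range(nc):
            for c in range(nc):
                c0 = (a * nc + b) * nc + c
                i0 = count[c0]
                i1 = count[c0 + 1]
                for o in range(14):
                    if o == 13:
                        j0 = i0
                        j1 = i1
                    else:
                        a2 = (a + offs[o, 0]) % nc
                        b2 = (b + offs[o, 1]) % nc
                        c2 = (c + offs[o, 2]) % nc
                        c1 = (a2 * nc + b2) * nc + c2
                        j0 = count[c1]
                        j1 = count[c1 + 1]
                    for ii in range(i0, i1):
                        i = order[ii]
                        x = pos[i, 0]
                        y = pos[i, 1]
                        z = pos[i, 2]
                        ti = typ[i]
                        bi = bod[i]
                        jstart = ii + 1 if o == 13 else j0
                        for jj in range(jstart, j1):
                            j = order[jj]
                            bj = bod[j]
                            if bi >= 0 and bi == bj:
                                continue
                            if need_cargo and bi >= 0 and bj >= 0:
                                continue
                            if bi >= 0 and bj >= 0 and bodfix[bi] == 1 \
                                    and bodfix[bj] == 1:
                                continue
                            tj = typ[j]
                            kd = kind[ti, tj]
                            if kd == 0:
                                continue
                            dx = _min_image(x - pos[j, 0], box)
                            dy = _min_image(y - pos[j, 1], box)
                            dz = _min_image(z - pos[j, 2], box)
                            if dx * dx + dy * dy + dz * dz < rcutb2[ti, tj]:
                                if cnt >= cap:
                                    return -1
                                pi[cnt] = i
                                pj[cnt] = j
                                pk[cnt] = kd
                                pe[cnt] = eps[ti, tj]
                                pp[cnt] = par[ti, tj]
                                pq[cnt] = req[ti, tj]
                                pr2[cnt] = rcut2[ti, tj]
                                ps[cnt] = shift[ti, tj]
                                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def ef_pairs_lin(pos, box, npairs, pi, pj, pk, pe, pp, pq, pr2, ps, F):
    E = 0.0
    F[:] = 0.0
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= pr2[p]:
            continue
        e, fr = pair_ef(pk[p], pe[p], pp[p], pq[p], pr2[p], ps[p], r2)
        E += e
        F[i, 0] += fr * dx
        F[i, 1] += fr * dy
        F[i, 2] += fr * dz
        F[j, 0] -= fr * dx
        F[j, 1] -= fr * dy
        F[j, 2] -= fr * dz
    return E


@njit(cache=True)
def max_displacement2(pos, ref, box):
    n = pos.shape[0]
    m = 0.0
    for i in range(n):
        dx = _min_image(pos[i, 0] - ref[i, 0], box)
        dy = _min_image(pos[i, 1] - ref[i, 1], box)
        dz = _min_image(pos[i, 2] - ref[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > m:
            m = r2
    return m
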