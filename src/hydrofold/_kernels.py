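"""Numba kernels: incremental energy/volume bookkeeping and the MC moves.

The Monte Carlo inner loop attempts thousands of single-variable updates per
step, so the hot path is compiled with numba.  The kernels maintain exact
integer bookkeeping of every extensive count the Hamiltonian needs:

* ``counts[0:4]``  raw sigma-matching NN water pairs per shell class
  (bulk, phi, zeta, chi) -- the HB counts before the global density factor;
* ``counts[4:8]``  raw cooperative pair counts per class of the molecule;
* ``counts[8:10]`` residue-water faces (phi, zeta);
* ``pair_hist``    water-water pair counts by squared lattice separation,
  which makes the LJ energy a 37-term dot product for any cell volume;
* ``fstate[IF_EMJ]`` the running Miyazawa-Jernigan contact energy.

Counts are integers, so incremental updates cannot drift; energies and
volumes are always *derived* from the counts.  Occupancy-changing moves
(protein moves) recompute the affected neighbourhood before and after the
change; rejected moves are reverted exactly, restoring bit-identical state.

Shared scalars live in two small arrays:
``fstate = [v, E_mj, T*, P*, delta_max, n_threshold]`` and
``istate = [L, Np, q, ni, stamp_ctr, stamp2_ctr, volume_flag, nmax]``.
Grouped array tuples keep the signatures manageable::

    G = (hydro, occ_chain, occ_res, sigma, labels)          # grids
    C = (cx, cy, clen, aa, hyd_seq, native)                 # chains
    E = (mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw)  # energetics
    W = (fstate, istate, stamp, stamp2, regx, regy, moved_mask,
         sx, sy, remx, remy, addx, addy, acc)               # workspace

``acc`` tallies attempts/acceptances per move kind
(0 shift, 1 rotation, 2 crankshaft, 3 pivot, 4 corner, 5 sigma, 6 volume).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fstate indices
IF_V, IF_EMJ, IF_T, IF_P, IF_DMAX, IF_NTHR = 0, 1, 2, 3, 4, 5
# istate indices
II_L, II_NP, II_Q, II_NI, II_CTR, II_CTR2, II_VOL, II_NMAX, II_PROT = (
    0, 1, 2, 3, 4, 5, 6, 7, 8,
)

MAX_D2 = 36
BIG = 1.0e100

# move kind ids in the acceptance tally
K_SHIFT, K_ROT, K_CRANK, K_PIVOT, K_CORNER, K_SIGMA, K_VOLUME = 0, 1, 2, 3, 4, 5, 6

DX = np.array([1, -1, 0, 0], dtype=np.int64)
DY = np.array([0, 0, 1, -1], dtype=np.int64)
OPP = np.array([1, 0, 3, 2], dtype=np.int64)


def _make_offsets() -> np.ndarray:
    offs = []
    for dx in range(-6, 7):
        for dy in range(-6, 7):
            d2 = dx * dx + dy * dy
            if 0 < d2 <= MAX_D2:
                offs.append((dx, dy, d2))
    return np.array(offs, dtype=np.int64)


OFFSETS = _make_offsets()


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def u_of(d2, v):
    """Truncated LJ for a pair at squared lattice separation d2, cell volume v."""
    dist2 = d2 * v  # (d * r)^2 with r = sqrt(v/h), h = 1
    if dist2 <= 1.0:
        return BIG
    if dist2 >= 36.0:
        return 0.0
    inv6 = 1.0 / (dist2 * dist2 * dist2)
    return 4.0 * (inv6 * inv6 - inv6)


@njit(cache=True)
def build_u_tab(u_tab, v):
    u_tab[0] = 0.0
    for d2 in range(1, MAX_D2 + 1):
        u_tab[d2] = u_of(d2, v)


@njit(cache=True, inline="always")
def cell_label(hydro, L, x, y):
    """Shell label of a water cell: 0 bulk, 1 phi, 2 zeta, 3 chi."""
    phi = False
    zeta = False
    for d in range(4):
        ny = y + DY[d]
        if ny < 0 or ny >= L:
            phi = True  # wall counts as hydrophobic
            continue
        h = hydro[(x + DX[d]) % L, ny]
        if h == 1:
            phi = True
        elif h == 2:
            zeta = True
    if phi and zeta:
        return 3
    if phi:
        return 1
    if zeta:
        return 2
    return 0


@njit(cache=True)
def rebuild_labels(hydro, labels, L):
    """Recompute the cached shell label of every water cell (residues: 0)."""
    for x in range(L):
        for y in range(L):
            labels[x, y] = cell_label(hydro, L, x, y) if hydro[x, y] == 0 else 0


@njit(cache=True, inline="always")
def _relabel_region(hydro, labels, L, regx, regy, nreg):
    for t in range(nreg):
        x = regx[t]
        y = regy[t]
        labels[x, y] = cell_label(hydro, L, x, y) if hydro[x, y] == 0 else 0


@njit(cache=True, inline="always")
def pair_label(la, lb):
    """HB class from its endpoint labels: bulk endpoint wins, mixed -> chi."""
    if la == 0 or lb == 0:
        return 0
    if la == lb:
        return la
    return 3


@njit(cache=True, inline="always")
def coop_pairs(s0, s1, s2, s3):
    n = 0
    if s0 == s1:
        n += 1
    if s0 == s2:
        n += 1
    if s0 == s3:
        n += 1
    if s1 == s2:
        n += 1
    if s1 == s3:
        n += 1
    if s2 == s3:
        n += 1
    return n


# --------------------------------------------------------------------------
# LJ pair bookkeeping
# --------------------------------------------------------------------------

@njit(cache=True)
def _water_pair_sum(hydro, pair_hist, u_tab, L, x, y, delta):
    """Pair energy of a water at (x, y) with all current waters; applies
    ``delta`` (+1/-1) to the pair histogram.  Returns the summed energy."""
    s = 0.0
    if L > 13:
        for k in range(OFFSETS.shape[0]):
            ny = y + OFFSETS[k, 1]
            if ny < 0 or ny >= L:
                continue
            nx = (x + OFFSETS[k, 0]) % L
            if hydro[nx, ny] == 0:
                d2 = OFFSETS[k, 2]
                s += u_tab[d2]
                pair_hist[d2] += delta
    else:
        for ox in range(L):
            for oy in range(L):
                if hydro[ox, oy] != 0 or (ox == x and oy == y):
                    continue
                dx = ox - x
                if dx < 0:
                    dx = -dx
                if L - dx < dx:
                    dx = L - dx
                d2 = dx * dx + (oy - y) * (oy - y)
                if d2 <= MAX_D2:
                    s += u_tab[d2]
                    pair_hist[d2] += delta
    return s


@njit(cache=True, inline="always")
def _remove_water(hydro, pair_hist, u_tab, L, x, y):
    """Take the water at (x, y) out of the LJ pair set (marks the cell)."""
    s = _water_pair_sum(hydro, pair_hist, u_tab, L, x, y, -1)
    hydro[x, y] = 3  # transient non-water marker, overwritten by the caller
    return s


@njit(cache=True, inline="always")
def _add_water(hydro, pair_hist, u_tab, L, x, y):
    """Turn the (non-water) cell at (x, y) into water in the LJ pair set."""
    s = _water_pair_sum(hydro, pair_hist, u_tab, L, x, y, +1)
    hydro[x, y] = 0
    return s


# --------------------------------------------------------------------------
# full recomputation (initialisation / bookkeeping audits)
# --------------------------------------------------------------------------

@njit(cache=True)
def full_recount(G, C, E, W):
    """Rebuild counts, pair_hist and E_mj from the grids, from scratch."""
    hydro, occ_chain, occ_res, sigma, labels = G
    cx, cy, clen, aa, hyd_seq, native = C
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate = W[0], W[1]
    L = istate[II_L]
    rebuild_labels(hydro, labels, L)
    for i in range(10):
        counts[i] = 0
    for i in range(MAX_D2 + 1):
        pair_hist[i] = 0
    emj = 0.0
    for x in range(L):
        for y in range(L):
            if hydro[x, y] == 0:
                s = sigma[x, y]
                counts[4 + labels[x, y]] += coop_pairs(s[0], s[1], s[2], s[3])
            for d in range(2):  # canonical edges: +x (d=0) and +y (d=2)
                dd = 0 if d == 0 else 2
                ny = y + DY[dd]
                if ny >= L:
                    continue
                nx = (x + DX[dd]) % L
                ha = hydro[x, y]
                hb_ = hydro[nx, ny]
                if ha == 0 and hb_ == 0:
                    if sigma[x, y, dd] == sigma[nx, ny, OPP[dd]]:
                        counts[pair_label(labels[x, y], labels[nx, ny])] += 1
                elif ha == 0 or hb_ == 0:
                    h = hb_ if ha == 0 else ha
                    counts[8 if h == 1 else 9] += 1
                else:
                    ci = occ_chain[x, y]
                    cj = occ_chain[nx, ny]
                    ri = occ_res[x, y]
                    rj = occ_res[nx, ny]
                    if not (ci == cj and (ri - rj == 1 or rj - ri == 1)):
                        emj += mj[aa[ci, ri], aa[cj, rj]]
    fstate[IF_EMJ] = emj
    # LJ pair histogram
    if L > 13:
        for x in range(L):
            for y in range(L):
                if hydro[x, y] != 0:
                    continue
                me = x * L + y
                for k in range(OFFSETS.shape[0]):
                    ny = y + OFFSETS[k, 1]
                    if ny < 0 or ny >= L:
                        continue
                    nx = (x + OFFSETS[k, 0]) % L
                    if hydro[nx, ny] == 0 and nx * L + ny > me:
                        pair_hist[OFFSETS[k, 2]] += 1
    else:
        for x1 in range(L):
            for y1 in range(L):
                if hydro[x1, y1] != 0:
                    continue
                for x2 in range(L):
                    for y2 in range(L):
                        if hydro[x2, y2] != 0 or x2 * L + y2 <= x1 * L + y1:
                            continue
                        dx = x1 - x2
                        if dx < 0:
                            dx = -dx
                        if L - dx < dx:
                            dx = L - dx
                        d2 = dx * dx + (y1 - y2) * (y1 - y2)
                        if d2 <= MAX_D2:
                            pair_hist[d2] += 1


@njit(cache=True)
def lj_from_hist(pair_hist, u_tab):
    s = 0.0
    for d2 in range(1, MAX_D2 + 1):
        if pair_hist[d2] > 0:
            s += pair_hist[d2] * u_tab[d2]
    return s


@njit(cache=True)
def total_energy(E, W):
    """Enthalpy derived from the bookkept counts."""
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate = W[0], W[1]
    ni = istate[II_NI]
    e = lj_from_hist(pair_hist, u_tab) + fstate[IF_EMJ]
    e -= epw[1] * counts[8] + epw[2] * counts[9]
    if ni == 1:
        for c in range(4):
            e -= jhb[c] * counts[c] + jco[c] * counts[4 + c]
    return e


@njit(cache=True)
def total_volume_k(E, W):
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate = W[0], W[1]
    L = istate[II_L]
    vtot = L * L * fstate[IF_V]
    if istate[II_NI] == 1:
        for c in range(4):
            vtot += vhb[c] * counts[c]
    return vtot


# --------------------------------------------------------------------------
# sigma flip
# --------------------------------------------------------------------------

@njit(cache=True)
def attempt_sigma_flip(G, C, E, W, x, y, d, s_new):
    """Metropolis update of one bonding variable; ``s_new <= 0`` draws it.

    Returns (accepted, dH, dV)."""
    hydro, occ_chain, occ_res, sigma, labels = G
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate = W[0], W[1]
    acc = W[13]
    L = istate[II_L]
    ni = istate[II_NI]
    acc[K_SIGMA, 0] += 1
    if s_new <= 0:
        s_new = 1 + np.random.randint(istate[II_Q])
    s_old = sigma[x, y, d]
    lab = labels[x, y]
    s = sigma[x, y]
    co_old = coop_pairs(s[0], s[1], s[2], s[3])
    t0, t1, t2, t3 = s[0], s[1], s[2], s[3]
    if d == 0:
        t0 = s_new
    elif d == 1:
        t1 = s_new
    elif d == 2:
        t2 = s_new
    else:
        t3 = s_new
    co_new = coop_pairs(t0, t1, t2, t3)
    dco = co_new - co_old
    # HB on the flipped face
    dhb = 0
    ec = 0
    ny = y + DY[d]
    if 0 <= ny < L:
        nx = (x + DX[d]) % L
        if hydro[nx, ny] == 0:
            facing = sigma[nx, ny, OPP[d]]
            ec = pair_label(lab, labels[nx, ny])
            dhb = (1 if s_new == facing else 0) - (1 if s_old == facing else 0)
    dH = 0.0
    dV = 0.0
    if ni == 1:
        dH = -(jhb[ec] * dhb + jco[lab] * dco)
        dV = vhb[ec] * dhb
    a = -(dH + fstate[IF_P] * dV) / fstate[IF_T]
    if a >= 0.0 or (a > -700.0 and np.random.random() < np.exp(a)):
        sigma[x, y, d] = s_new
        counts[ec] += dhb
        counts[4 + lab] += dco
        acc[K_SIGMA, 1] += 1
        return True, dH, dV
    return False, 0.0, 0.0


# --------------------------------------------------------------------------
# occupancy-changing moves (protein moves)
# --------------------------------------------------------------------------

@njit(cache=True)
def _region_tally(G, C, E, W, nreg, buf):
    """HB / coop / pw counts and MJ energy restricted to the stamped region.

    Edges incident to the region are counted once: interior edges from their
    lower flat-id endpoint, boundary edges from their region endpoint.
    Writes the 10 integer tallies into ``buf`` and returns the MJ part.
    """
    hydro, occ_chain, occ_res, sigma, labels = G
    cx, cy, clen, aa, hyd_seq, native = C
    mj = E[0]
    fstate, istate, stamp = W[0], W[1], W[2]
    regx, regy = W[4], W[5]
    L = istate[II_L]
    cur = istate[II_CTR]
    for i in range(10):
        buf[i] = 0
    emj = 0.0
    for t in range(nreg):
        x = regx[t]
        y = regy[t]
        ha = hydro[x, y]
        if ha == 0:
            s = sigma[x, y]
            buf[4 + labels[x, y]] += coop_pairs(s[0], s[1], s[2], s[3])
        me = x * L + y
        for d in range(4):
            ny = y + DY[d]
            if ny < 0 or ny >= L:
                continue
            nx = (x + DX[d]) % L
            if stamp[nx, ny] == cur and nx * L + ny < me:
                continue  # interior edge handled from the other endpoint
            hb_ = hydro[nx, ny]
            if ha == 0 and hb_ == 0:
                if sigma[x, y, d] == sigma[nx, ny, OPP[d]]:
                    buf[pair_label(labels[x, y], labels[nx, ny])] += 1
            elif ha == 0 or hb_ == 0:
                h = hb_ if ha == 0 else ha
                buf[8 if h == 1 else 9] += 1
            else:
                ci = occ_chain[x, y]
                cj = occ_chain[nx, ny]
                ri = occ_res[x, y]
                rj = occ_res[nx, ny]
                if not (ci == cj and (ri - rj == 1 or rj - ri == 1)):
                    emj += mj[aa[ci, ri], aa[cj, rj]]
    return emj


@njit(cache=True)
def _stamp_region(G, W, oldx, oldy, nm, px, py):
    """Stamp the moved cells (old wrapped + new wrapped) plus neighbours."""
    fstate, istate, stamp = W[0], W[1], W[2]
    regx, regy = W[4], W[5]
    L = istate[II_L]
    istate[II_CTR] += 1
    cur = istate[II_CTR]
    nreg = 0
    for src in range(2):
        for t in range(nm):
            if src == 0:
                x0 = oldx[t] % L
                y0 = oldy[t]
            else:
                x0 = px[t] % L
                y0 = py[t]
            for k in range(5):
                if k == 4:
                    x, y = x0, y0
                else:
                    y = y0 + DY[k]
                    if y < 0 or y >= L:
                        continue
                    x = (x0 + DX[k]) % L
                if stamp[x, y] != cur:
                    stamp[x, y] = cur
                    regx[nreg] = x
                    regy[nreg] = y
                    nreg += 1
    return nreg


@njit(cache=True)
def attempt_chain_move(G, C, E, W, kind, ci, idx, nm, px, py, buf_a, buf_b):
    """Propose moving ``nm`` residues of chain ``ci`` to unwrapped (px, py).

    Generic engine behind shift/rotation/crankshaft/pivot/corner moves:
    validates excluded volume, retallies the affected neighbourhood, applies
    Metropolis and reverts exactly on rejection.  Returns (accepted, dH, dV).
    """
    hydro, occ_chain, occ_res, sigma, labels = G
    cx, cy, clen, aa, hyd_seq, native = C
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate, stamp, stamp2 = W[0], W[1], W[2], W[3]
    moved_mask, sx, sy = W[6], W[7], W[8]
    remx, remy, addx, addy = W[9], W[10], W[11], W[12]
    acc = W[13]
    L = istate[II_L]
    ni = istate[II_NI]
    acc[kind, 0] += 1

    for t in range(nm):
        moved_mask[idx[t]] = 1
    istate[II_CTR2] += 1
    cur2 = istate[II_CTR2]
    ok = True
    for t in range(nm):
        y = py[t]
        if y < 0 or y >= L:
            ok = False
            break
        x = px[t] % L
        oc = occ_chain[x, y]
        if oc >= 0 and not (oc == ci and moved_mask[occ_res[x, y]] == 1):
            ok = False
            break
        if stamp2[x, y] == cur2:
            ok = False  # two proposed residues on the same wrapped cell
            break
        stamp2[x, y] = cur2
    if not ok:
        for t in range(nm):
            moved_mask[idx[t]] = 0
        return False, 0.0, 0.0

    # old coordinates (unwrapped) of the moved residues
    for t in range(nm):
        sx[t] = cx[ci, idx[t]]
        sy[t] = cy[ci, idx[t]]

    nreg = _stamp_region(G, W, sx, sy, nm, px, py)
    emj_a = _region_tally(G, C, E, W, nreg, buf_a)

    # ---- apply ----
    dU = 0.0
    nrem = 0
    # new cells that currently hold water leave the water set
    for t in range(nm):
        x = px[t] % L
        y = py[t]
        if hydro[x, y] == 0:
            dU -= _remove_water(hydro, pair_hist, u_tab, L, x, y)
            remx[nrem] = x
            remy[nrem] = y
            nrem += 1
    # old cells not re-occupied become water
    nadd = 0
    for t in range(nm):
        x = sx[t] % L
        y = sy[t]
        if stamp2[x, y] != cur2:  # not among the proposed cells
            occ_chain[x, y] = -1
            occ_res[x, y] = -1
            dU += _add_water(hydro, pair_hist, u_tab, L, x, y)
            addx[nadd] = x
            addy[nadd] = y
            nadd += 1
    # write the residues at their proposed cells
    for t in range(nm):
        x = px[t] % L
        y = py[t]
        occ_chain[x, y] = ci
        occ_res[x, y] = idx[t]
        hydro[x, y] = hyd_seq[ci, idx[t]]
        cx[ci, idx[t]] = px[t]
        cy[ci, idx[t]] = py[t]
    regx, regy = W[4], W[5]
    _relabel_region(hydro, labels, L, regx, regy, nreg)

    emj_b = _region_tally(G, C, E, W, nreg, buf_b)

    dH = dU + (emj_b - emj_a)
    dH -= epw[1] * (buf_b[8] - buf_a[8]) + epw[2] * (buf_b[9] - buf_a[9])
    dV = 0.0
    if ni == 1:
        for c in range(4):
            dH -= jhb[c] * (buf_b[c] - buf_a[c]) + jco[c] * (buf_b[4 + c] - buf_a[4 + c])
            dV += vhb[c] * (buf_b[c] - buf_a[c])
    a = -(dH + fstate[IF_P] * dV) / fstate[IF_T]
    if a >= 0.0 or (a > -700.0 and np.random.random() < np.exp(a)):
        for c in range(10):
            counts[c] += buf_b[c] - buf_a[c]
        fstate[IF_EMJ] += emj_b - emj_a
        for t in range(nm):
            moved_mask[idx[t]] = 0
        acc[kind, 1] += 1
        return True, dH, dV

    # ---- revert ----
    for t in range(nadd):
        _remove_water(hydro, pair_hist, u_tab, L, addx[t], addy[t])
    for t in range(nm):
        x = px[t] % L
        y = py[t]
        occ_chain[x, y] = -1
        occ_res[x, y] = -1
    for t in range(nm):
        x = sx[t] % L
        y = sy[t]
        occ_chain[x, y] = ci
        occ_res[x, y] = idx[t]
        hydro[x, y] = hyd_seq[ci, idx[t]]
        cx[ci, idx[t]] = sx[t]
        cy[ci, idx[t]] = sy[t]
    for t in range(nrem):
        _add_water(hydro, pair_hist, u_tab, L, remx[t], remy[t])
    _relabel_region(hydro, labels, L, regx, regy, nreg)
    for t in range(nm):
        moved_mask[idx[t]] = 0
    return False, 0.0, 0.0


# --------------------------------------------------------------------------
# proposal generators
# --------------------------------------------------------------------------

@njit(cache=True)
def propose_global(C, W, kind, ci, idx, px, py):
    """Fill (idx, px, py) for a global move of chain ``ci``; returns nm.

    shift: whole-chain translation by one lattice unit; rotation: whole-chain
    rotation by 90/180/270 degrees about a uniformly chosen residue;
    crankshaft: 180-degree flip of a two-residue U-turn; pivot: a random
    non-identity lattice isometry applied from a uniformly chosen residue to
    a random chain end.  Every kernel is symmetric (closed under inverses).
    """
    cx, cy, clen = C[0], C[1], C[2]
    n = clen[ci]
    if kind == K_SHIFT:
        d = np.random.randint(4)
        for i in range(n):
            idx[i] = i
            px[i] = cx[ci, i] + DX[d]
            py[i] = cy[ci, i] + DY[d]
        return n
    if kind == K_ROT:
        k = np.random.randint(n)
        rot = 1 + np.random.randint(3)
        x0 = cx[ci, k]
        y0 = cy[ci, k]
        for i in range(n):
            rx = cx[ci, i] - x0
            ry = cy[ci, i] - y0
            for _ in range(rot):
                rx, ry = -ry, rx
            idx[i] = i
            px[i] = x0 + rx
            py[i] = y0 + ry
        return n
    if kind == K_CRANK:
        if n < 4:
            return 0
        i = 1 + np.random.randint(n - 3)  # first of the two flipped residues
        ux = cx[ci, i] - cx[ci, i - 1]
        uy = cy[ci, i] - cy[ci, i - 1]
        # U-turn: the chain re-enters the base line two bonds later
        if cx[ci, i + 2] - cx[ci, i + 1] != -ux or cy[ci, i + 2] - cy[ci, i + 1] != -uy:
            return 0
        if cx[ci, i + 1] - cx[ci, i] == ux and cy[ci, i + 1] - cy[ci, i] == uy:
            return 0  # straight segment, no U
        idx[0] = i
        px[0] = cx[ci, i] - 2 * ux
        py[0] = cy[ci, i] - 2 * uy
        idx[1] = i + 1
        px[1] = cx[ci, i + 1] - 2 * ux
        py[1] = cy[ci, i + 1] - 2 * uy
        return 2
    # pivot
    k = np.random.randint(n)
    tail = np.random.randint(2) == 1
    g = 1 + np.random.randint(7)  # non-identity square-lattice isometries
    x0 = cx[ci, k]
    y0 = cy[ci, k]
    nm = 0
    lo = k + 1 if tail else 0
    hi = n if tail else k
    for i in range(lo, hi):
        rx = cx[ci, i] - x0
        ry = cy[ci, i] - y0
        if g == 1:
            rx, ry = -ry, rx
        elif g == 2:
            rx, ry = -rx, -ry
        elif g == 3:
            rx, ry = ry, -rx
        elif g == 4:
            rx = -rx
        elif g == 5:
            ry = -ry
        elif g == 6:
            rx, ry = ry, rx
        else:
            rx, ry = -ry, -rx
        idx[nm] = i
        px[nm] = x0 + rx
        py[nm] = y0 + ry
        nm += 1
    return nm


@njit(cache=True)
def propose_corner(G, C, W, x, y, idx, px, py):
    """Corner flip of the residue at wrapped cell (x, y); returns nm (0/1)."""
    hydro, occ_chain, occ_res = G[0], G[1], G[2]
    cx, cy, clen = C[0], C[1], C[2]
    ci = occ_chain[x, y]
    ri = occ_res[x, y]
    n = clen[ci]
    if ri == 0 or ri == n - 1:
        return 0, ci
    ax, ay = cx[ci, ri - 1], cy[ci, ri - 1]
    bx, by = cx[ci, ri + 1], cy[ci, ri + 1]
    if ax == bx or ay == by:
        return 0, ci  # straight segment, no bend
    idx[0] = ri
    px[0] = ax + bx - cx[ci, ri]
    py[0] = ay + by - cy[ci, ri]
    return 1, ci


# --------------------------------------------------------------------------
# volume move
# --------------------------------------------------------------------------

@njit(cache=True)
def attempt_volume_move(G, C, E, W, dv):
    """Global volume update; ``dv = nan`` draws uniform(-dmax, +dmax)."""
    mj, counts, pair_hist, u_tab, jhb, jco, vhb, epw = E
    fstate, istate = W[0], W[1]
    acc = W[13]
    L = istate[II_L]
    acc[K_VOLUME, 0] += 1
    if np.isnan(dv):
        dv = (2.0 * np.random.random() - 1.0) * fstate[IF_DMAX]
    v_old = fstate[IF_V]
    v_new = v_old + dv
    if v_new < 1.0:
        return False, 0.0, 0.0
    ni_old = istate[II_NI]
    ni_new = 1 if v_new < fstate[IF_NTHR] else 0
    du = 0.0
    for d2 in range(1, MAX_D2 + 1):
        if pair_hist[d2] > 0:
            du += pair_hist[d2] * (u_of(d2, v_new) - u_tab[d2])
    dhb = 0.0
    dvol_hb = 0.0
    if ni_new != ni_old:
        s_e = 0.0
        s_v = 0.0
        for c in range(4):
            s_e += jhb[c] * counts[c] + jco[c] * counts[4 + c]
            s_v += vhb[c] * counts[c]
        dhb = -(ni_new - ni_old) * s_e
        dvol_hb = (ni_new - ni_old) * s_v
    dH = du + dhb
    dV = L * L * (v_new - v_old) + dvol_hb
    a = -(dH + fstate[IF_P] * dV) / fstate[IF_T]
    if a >= 0.0 or (a > -700.0 and np.random.random() < np.exp(a)):
        fstate[IF_V] = v_new
        istate[II_NI] = ni_new
        build_u_tab(u_tab, v_new)
        acc[K_VOLUME, 1] += 1
        return True, dH, dV
    return False, 0.0, 0.0


# --------------------------------------------------------------------------
# one MC step and the run loop
# --------------------------------------------------------------------------

@njit(cache=True)
def mc_step(G, C, E, W, idx, px, py, buf_a, buf_b):
    """One full MC step: Np global-move attempts of one randomly drawn kind,
    m ~ U[1, 4L^2] local attempts (corner flips on residues, sigma flips on
    water), then one volume-move attempt."""
    hydro = G[0]
    fstate, istate = W[0], W[1]
    L = istate[II_L]
    Np = istate[II_NP]
    frozen = istate[II_PROT] == 0
    if Np > 0 and not frozen:
        kind = np.random.randint(4)
        for _ in range(Np):
            ci = np.random.randint(Np)
            nm = propose_global(C, W, kind, ci, idx, px, py)
            if nm > 0:
                attempt_chain_move(G, C, E, W, kind, ci, idx, nm, px, py, buf_a, buf_b)
            else:
                W[13][kind, 0] += 1  # infeasible proposal counts as an attempt
    m = 1 + np.random.randint(4 * L * L)
    for _ in range(m):
        x = np.random.randint(L)
        y = np.random.randint(L)
        if hydro[x, y] == 0:
            d = np.random.randint(4)
            attempt_sigma_flip(G, C, E, W, x, y, d, 0)
        elif frozen:
            pass  # protein degrees of freedom disabled (oracle comparisons)
        else:
            nm, ci = propose_corner(G, C, W, x, y, idx, px, py)
            if nm > 0:
                attempt_chain_move(G, C, E, W, K_CORNER, ci, idx, nm, px, py, buf_a, buf_b)
            else:
                W[13][K_CORNER, 0] += 1
    if istate[II_VOL] == 1:
        attempt_volume_move(G, C, E, W, np.nan)


@njit(cache=True)
def count_observables(G, C, W):
    """(native contacts, inter-chain + wall contacts, wall contacts), raw."""
    hydro, occ_chain, occ_res = G[0], G[1], G[2]
    native = C[5]
    istate = W[1]
    L = istate[II_L]
    nat = 0
    inter = 0
    wall = 0
    for x in range(L):
        for y in range(L):
            ci = occ_chain[x, y]
            if ci < 0:
                continue
            ri = occ_res[x, y]
            if y == 0 or y == L - 1:
                wall += 1
            for d in (0, 2):  # canonical +x, +y edges
                ny = y + DY[d]
                if ny >= L:
                    continue
                nx = (x + DX[d]) % L
                cj = occ_chain[nx, ny]
                if cj < 0:
                    continue
                rj = occ_res[nx, ny]
                if cj == ci:
                    if ri - rj != 1 and rj - ri != 1 and native[ri, rj]:
                        nat += 1
                else:
                    inter += 1
    return nat, inter + wall, wall


@njit(cache=True)
def run_steps(G, C, E, W, idx, px, py, buf_a, buf_b, n_steps, stride, step0, rec):
    """Advance ``n_steps``; record observables every ``stride`` steps.

    ``rec`` columns: step, raw native / inter / wall contact counts,
    ni-weighted NHB per class, enthalpy, total volume, v."""
    fstate, istate = W[0], W[1]
    counts = E[1]
    nrec = 0
    for s in range(n_steps):
        mc_step(G, C, E, W, idx, px, py, buf_a, buf_b)
        if (s + 1) % stride == 0:
            nat, ic, mc = count_observables(G, C, W)
            ni = istate[II_NI]
            rec[nrec, 0] = step0 + s + 1
            rec[nrec, 1] = nat
            rec[nrec, 2] = ic
            rec[nrec, 3] = mc
            for c in range(4):
                rec[nrec, 4 + c] = ni * counts[c]
            rec[nrec, 8] = total_energy(E, W)
            rec[nrec, 9] = total_volume_k(E, W)
            rec[nrec, 10] = fstate[IF_V]
            nrec += 1
    return nrec
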