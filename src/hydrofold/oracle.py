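"""Exact Boltzmann enumeration for tiny water systems.

For a frozen-occupancy, fixed-volume state with at most three water cells
(twelve bonding variables, ``6^12`` joint states) the partition function can
be enumerated outright, giving exact averages of the HB counts, cooperative
counts and enthalpy.  These serve as the independent oracle the Monte Carlo
sampler is validated against; the enumeration shares no code with the
sampler's bookkeeping.

Each water cell contributes a per-cell cooperative energy (a function of its
own four bonding variables only) and each facing water-water pair an HB
energy when the two facing variables match; everything else in the enthalpy
is constant under sigma moves and is added back from the reference
energetics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .energetics import density_index, lj_total, protein_contact_energy, protein_water_energy
from .lattice import WATER, LatticeState, classify_hb_pair, classify_water
from .parameters import ModelParameters

__all__ = ["enumerate_exact"]

MAX_SIGMA_DOF = 12

_NSTATES = 6**4  # joint states of one cell's four bonding variables


def _cell_tables(q: int = 6):
    """Per-cell lookup tables: cooperative pair count and face digits."""
    ct = np.zeros(_NSTATES, dtype=np.int64)
    fd = np.zeros((_NSTATES, 4), dtype=np.int64)
    for s in range(_NSTATES):
        d = [(s // q**k) % q for k in range(4)]
        fd[s] = d
        ct[s] = sum(1 for a in range(4) for b in range(a + 1, 4) if d[a] == d[b])
    return ct, fd


@njit(cache=True)
def _enum(ncells, ct, fd, e_i, e_j, e_di, e_dj, jcell, lab, ej, ec, beta):
    """Enumerate all joint cell states; returns Z-normalized averages."""
    Z = 0.0
    e_acc = 0.0
    e2_acc = 0.0
    hb2_acc = 0.0
    co2_acc = 0.0
    nhb = np.zeros(4)
    nco = np.zeros(4)
    ne = e_i.shape[0]
    n1 = _NSTATES
    n2 = _NSTATES if ncells > 1 else 1
    n3 = _NSTATES if ncells > 2 else 1
    for s0 in range(n1):
        e0 = -jcell[0] * ct[s0]
        for s1 in range(n2):
            e01 = e0
            if ncells > 1:
                e01 -= jcell[1] * ct[s1]
            for s2 in range(n3):
                e = e01
                if ncells > 2:
                    e -= jcell[2] * ct[s2]
                for k in range(ne):
                    si = s0 if e_i[k] == 0 else (s1 if e_i[k] == 1 else s2)
                    sj = s0 if e_j[k] == 0 else (s1 if e_j[k] == 1 else s2)
                    if fd[si, e_di[k]] == fd[sj, e_dj[k]]:
                        e -= ej[k]
                w = np.exp(-beta * e)
                Z += w
                e_acc += w * e
                e2_acc += w * e * e
                co_tot = ct[s0]
                nco[lab[0]] += w * ct[s0]
                if ncells > 1:
                    nco[lab[1]] += w * ct[s1]
                    co_tot += ct[s1]
                if ncells > 2:
                    nco[lab[2]] += w * ct[s2]
                    co_tot += ct[s2]
                co2_acc += w * co_tot * co_tot
                hb_tot = 0
                for k in range(ne):
                    si = s0 if e_i[k] == 0 else (s1 if e_i[k] == 1 else s2)
                    sj = s0 if e_j[k] == 0 else (s1 if e_j[k] == 1 else s2)
                    if fd[si, e_di[k]] == fd[sj, e_dj[k]]:
                        nhb[ec[k]] += w
                        hb_tot += 1
                hb2_acc += w * hb_tot * hb_tot
    return Z, e_acc / Z, nhb / Z, nco / Z, e2_acc / Z, hb2_acc / Z, co2_acc / Z


def enumerate_exact(state: LatticeState, params: ModelParameters) -> dict:
    """Exact averages over all bonding-variable states of a tiny system.

    Requires at most :data:`MAX_SIGMA_DOF` sigma degrees of freedom (three
    water cells); larger systems are refused with a size report.  Returns a
    dict with ``NHB`` and ``Ncoop`` per class [bulk, phi, zeta, chi], the
    mean enthalpy ``E`` (including the sigma-independent LJ, MJ and
    residue-water constants) and the sigma-independent constant itself.
    """
    L = state.L
    waters = [
        (x, y) for x in range(L) for y in range(L) if state.hydro[x, y] == WATER
    ]
    dof = 4 * len(waters)
    if dof > MAX_SIGMA_DOF:
        raise ValueError(
            f"state has {len(waters)} water cells = {dof} sigma variables; "
            f"exact enumeration is limited to {MAX_SIGMA_DOF}"
        )
    if not waters:
        raise ValueError("no water cells to enumerate")
    ni = density_index(state, params)
    lab = np.array([classify_water(state, w) for w in waters], dtype=np.int64)
    jco = np.array([params.Jsig, params.Jsig_phi, params.Jsig_zeta, params.Jsig_chi])
    jhb = np.array([params.J, params.J_phi, params.J_zeta, params.J_chi])
    jcell = ni * jco[lab]

    index = {w: i for i, w in enumerate(waters)}
    dirs = ((1, 0, 0, 1), (0, 1, 2, 3))  # (+dx, +dy, face, opposite face)
    e_i, e_j, e_di, e_dj, ej, ec = [], [], [], [], [], []
    for (x, y), i in index.items():
        for dx, dy, di, dj in dirs:
            ny = y + dy
            if ny >= L:
                continue
            nb = ((x + dx) % L, ny)
            j = index.get(nb)
            if j is not None:
                cls = classify_hb_pair(state, (x, y), nb)
                e_i.append(i)
                e_j.append(j)
                e_di.append(di)
                e_dj.append(dj)
                ej.append(ni * jhb[cls])
                ec.append(cls)
    ct, fd = _cell_tables(params.q)
    Z, e_sig, nhb, nco, e2, hb2, co2 = _enum(
        len(waters), ct, fd,
        np.array(e_i, dtype=np.int64), np.array(e_j, dtype=np.int64),
        np.array(e_di, dtype=np.int64), np.array(e_dj, dtype=np.int64),
        jcell, lab, np.array(ej, dtype=np.float64), np.array(ec, dtype=np.int64),
        1.0 / params.T_star,
    )
    from .protein import load_mj_matrix

    const = (
        lj_total(state, params)
        + protein_contact_energy(state, load_mj_matrix())
        + protein_water_energy(state, params)
    )
    return {
        "Z": Z,
        "E": e_sig + const,
        "E_sigma": e_sig,
        "E_const": const,
        "NHB": ni * nhb,
        "Ncoop": ni * nco,
        # exact thermal standard deviations of the sigma-dependent totals
        "sd_E": float(np.sqrt(max(0.0, e2 - e_sig**2))),
        "sd_NHB": float(ni * np.sqrt(max(0.0, hb2 - nhb.sum() ** 2))),
        "sd_Ncoop": float(ni * np.sqrt(max(0.0, co2 - nco.sum() ** 2))),
        "n_water": len(waters),
    }
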