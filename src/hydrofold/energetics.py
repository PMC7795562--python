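"""Reference evaluation of every Hamiltonian term, by full recomputation.

The enthalpy of a microstate splits into

* ``U_lj`` — double-truncated Lennard-Jones attraction between all water
  pairs closer than ``6 r0`` (hard core at ``r0``, zero beyond the cutoff);
  residues carry no LJ interaction;
* ``-J NHB(b) - Jsig Ncoop(b)`` — directional and cooperative hydrogen-bond
  terms of bulk water;
* the hydration-shell analogue with class-resolved couplings (phi / zeta /
  chi shells);
* the Miyazawa-Jernigan contact energy between non-bonded NN residues;
* the isotropic residue-water attraction (``-eps_phi`` / ``-eps_zeta`` per
  exposed face).

A NN water pair forms a HB iff the density index is on (``ni nj = 1``, a
global function of ``v/v0``) and the facing bonding variables match
(``sigma_ij = sigma_ji``).  Each molecule's cooperative count is the number
of equal-valued pairs among its four bonding variables (six pairs maximum),
including faces toward residues or walls, which never carry HBs themselves.

The total volume is ``V = L^2 v`` plus one ``vHB`` per HB, with the
hydrophobic-shell HB volume shrinking linearly with pressure.

These functions are deliberately simple and independent of the incremental
bookkeeping used by the Monte Carlo kernels; the two must agree to floating
point accuracy, which the test suite enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import BULK, CHI, PHI, WATER, ZETA, LatticeState, classify_hb_pair, classify_water
from .parameters import ModelParameters

__all__ = [
    "EnergyBreakdown",
    "VolumeBreakdown",
    "lj_potential",
    "lj_total",
    "water_pair_histogram",
    "hb_and_coop_counts",
    "hydration_energy",
    "protein_contact_energy",
    "protein_water_energy",
    "total_enthalpy",
    "total_volume",
]


@dataclass
class EnergyBreakdown:
    """Enthalpy components plus the HB/cooperative counts per shell class."""

    U_lj: float
    E_hb_bulk: float
    E_coop_bulk: float
    E_hb_shell: float
    E_coop_shell: float
    E_mj: float
    E_pw: float
    NHB: np.ndarray    # per class [bulk, phi, zeta, chi], ni-weighted
    Ncoop: np.ndarray  # per class, ni-weighted

    @property
    def total(self) -> float:
        return (
            self.U_lj
            + self.E_hb_bulk
            + self.E_coop_bulk
            + self.E_hb_shell
            + self.E_coop_shell
            + self.E_mj
            + self.E_pw
        )


@dataclass
class VolumeBreakdown:
    """Total volume: cells plus the HB contributions per class."""

    base: float    # L^2 * v
    V_hb: float    # bulk + zeta + chi HB volumes
    V_phi: float   # hydrophobic-shell HB volume, pressure dependent

    @property
    def total(self) -> float:
        return self.base + self.V_hb + self.V_phi


def density_index(state: LatticeState, params: ModelParameters) -> int:
    """Global HB density condition: 1 iff ``v/v0 < n_threshold``."""
    return int(state.v / params.v0 < params.n_threshold)


# --------------------------------------------------------------------------
# Lennard-Jones
# --------------------------------------------------------------------------

def lj_potential(r: float, params: ModelParameters) -> float:
    """Double-truncated LJ: hard core below r0, zero at and beyond 6 r0."""
    if r <= params.r0:
        return np.inf
    if r >= params.lj_cutoff * params.r0:
        return 0.0
    s = params.r0 / r
    return 4.0 * (s**12 - s**6)


def water_pair_histogram(state: LatticeState, max_d2: int = 36) -> np.ndarray:
    """Counts of unordered water-water pairs by squared lattice separation.

    Minimum image in x only (pairs never wrap across the walls); each pair
    counted once at its minimal image distance.
    """
    L = state.L
    xs, ys = np.nonzero(state.hydro == WATER)
    hist = np.zeros(max_d2 + 1, dtype=np.int64)
    dx = np.abs(xs[:, None] - xs[None, :])
    dx = np.minimum(dx, L - dx)
    d2 = dx**2 + (ys[:, None] - ys[None, :]) ** 2
    iu = np.triu_indices(len(xs), k=1)
    vals = d2[iu]
    vals = vals[vals <= max_d2]
    np.add.at(hist, vals, 1)
    return hist


def lj_total(state: LatticeState, params: ModelParameters) -> float:
    """Sum of the truncated LJ over all water pairs within the cutoff."""
    r = np.sqrt(state.v / params.h)
    hist = water_pair_histogram(state)
    total = 0.0
    for d2, n in enumerate(hist):
        if n:
            total += n * lj_potential(np.sqrt(d2) * r, params)
    return float(total)


# --------------------------------------------------------------------------
# hydrogen bonds and cooperativity
# --------------------------------------------------------------------------

def hb_and_coop_counts(
    state: LatticeState, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """(NHB, Ncoop) per shell class [bulk, phi, zeta, chi], ni-weighted."""
    L = state.L
    ni = density_index(state, params)
    nhb = np.zeros(4, dtype=np.int64)
    ncoop = np.zeros(4, dtype=np.int64)
    if ni == 0:
        return nhb, ncoop
    for x in range(L):
        for y in range(L):
            if state.hydro[x, y] != WATER:
                continue
            s = state.sigma[x, y]
            pairs = sum(
                1 for a in range(4) for b in range(a + 1, 4) if s[a] == s[b]
            )
            ncoop[classify_water(state, (x, y))] += pairs
            # HB on the +x face
            xr = (x + 1) % L
            if state.hydro[xr, y] == WATER and state.sigma[x, y, 0] == state.sigma[xr, y, 1]:
                nhb[classify_hb_pair(state, (x, y), (xr, y))] += 1
            # HB on the +y face
            if y + 1 < L and state.hydro[x, y + 1] == WATER:
                if state.sigma[x, y, 2] == state.sigma[x, y + 1, 3]:
                    nhb[classify_hb_pair(state, (x, y), (x, y + 1))] += 1
    return nhb, ncoop


def hydration_energy(
    nhb: np.ndarray, ncoop: np.ndarray, params: ModelParameters
) -> float:
    """Shell HB + cooperative energy (phi, zeta and chi classes)."""
    return -(
        params.J_phi * nhb[PHI]
        + params.J_zeta * nhb[ZETA]
        + params.J_chi * nhb[CHI]
        + params.Jsig_phi * ncoop[PHI]
        + params.Jsig_zeta * ncoop[ZETA]
        + params.Jsig_chi * ncoop[CHI]
    )


# --------------------------------------------------------------------------
# protein terms
# --------------------------------------------------------------------------

def protein_contact_energy(state: LatticeState, matrix: np.ndarray) -> float:
    """MJ energy over all non-bonded NN residue pairs (intra and inter chain)."""
    L = state.L
    total = 0.0
    aa = [c.sequence.aa_indices for c in state.chains]
    for x in range(L):
        for y in range(L):
            ci = state.occ_chain[x, y]
            if ci < 0:
                continue
            ri = state.occ_res[x, y]
            for nx, ny in (((x + 1) % L, y), (x, y + 1)):
                if ny >= L:
                    continue
                cj = state.occ_chain[nx, ny]
                if cj < 0:
                    continue
                rj = state.occ_res[nx, ny]
                if ci == cj and abs(int(ri) - int(rj)) == 1:
                    continue  # chain bond, not a contact
                total += matrix[aa[ci][ri], aa[cj][rj]]
    return float(total)


def protein_water_energy(state: LatticeState, params: ModelParameters) -> float:
    """Isotropic residue-water attraction; wall faces contribute nothing."""
    L = state.L
    n_phi = n_zeta = 0
    for x in range(L):
        for y in range(L):
            h = state.hydro[x, y]
            if h == WATER:
                continue
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny = y + dy
                if ny < 0 or ny >= L:
                    continue
                if state.hydro[(x + dx) % L, ny] == WATER:
                    if h == 1:
                        n_phi += 1
                    else:
                        n_zeta += 1
    return -params.eps_phi * n_phi - params.eps_zeta * n_zeta


# --------------------------------------------------------------------------
# totals
# --------------------------------------------------------------------------

def total_enthalpy(
    state: LatticeState, params: ModelParameters, matrix: np.ndarray
) -> EnergyBreakdown:
    """Full recomputation of every enthalpy component."""
    nhb, ncoop = hb_and_coop_counts(state, params)
    return EnergyBreakdown(
        U_lj=lj_total(state, params),
        E_hb_bulk=-params.J * float(nhb[BULK]),
        E_coop_bulk=-params.Jsig * float(ncoop[BULK]),
        E_hb_shell=-(
            params.J_phi * nhb[PHI] + params.J_zeta * nhb[ZETA] + params.J_chi * nhb[CHI]
        ),
        E_coop_shell=-(
            params.Jsig_phi * ncoop[PHI]
            + params.Jsig_zeta * ncoop[ZETA]
            + params.Jsig_chi * ncoop[CHI]
        ),
        E_mj=protein_contact_energy(state, matrix),
        E_pw=protein_water_energy(state, params),
        NHB=nhb,
        Ncoop=ncoop,
    )


def total_volume(state: LatticeState, params: ModelParameters) -> VolumeBreakdown:
    """Cell volume plus the HB volume contributions, per class."""
    nhb, _ = hb_and_coop_counts(state, params)
    return VolumeBreakdown(
        base=state.L**2 * state.v,
        V_hb=(nhb[BULK] + nhb[ZETA]) * params.vHB_b + nhb[CHI] * params.vHB_chi(),
        V_phi=nhb[PHI] * params.vHB_phi(),
    )
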