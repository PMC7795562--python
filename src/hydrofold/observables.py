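"""Folding/aggregation order parameters and free-energy profiles.

Three normalized observables track the state of the protein solution:

* ``Nc`` -- native contacts: current non-bonded NN residue pairs whose index
  pair belongs to the native contact map, summed over chains and divided by
  the maximum (25 per snake protein).  Contact-map identity makes ``Nc``
  invariant under rigid motions: a translated or rotated native snake still
  has ``Nc = 1``.
* ``Ic`` -- inter-contacts: NN residue pairs between *different* chains plus
  residue faces touching a wall, divided by 36 per protein.
* ``Mc`` -- wall contacts: residue faces adjacent to either confining wall,
  divided by ``2L``.

From a sampled time series the free energy along an observable is estimated
as ``F*(O) = -T* ln P(O)``, histogrammed on the observable's natural
quantum (1/(25 Np) for Nc, etc.), shifted so the global minimum is zero.
Empty bins are excluded rather than regularized: no pseudo-counts, no
smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeState

__all__ = [
    "compute_Nc",
    "compute_Ic",
    "compute_Mc",
    "FreeEnergyProfile",
    "free_energy_profile",
    "free_energy_surface",
    "find_minimum",
]


def _residue_contacts(state: LatticeState):
    """Yield (chain_i, res_i, chain_j, res_j) for unordered NN residue pairs."""
    L = state.L
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
                if cj >= 0:
                    yield int(ci), int(ri), int(cj), int(state.occ_res[nx, ny])


def compute_Nc(state: LatticeState) -> float:
    """Fraction of native contacts, summed over chains; 1.0 iff all native."""
    n = 0
    for ci, ri, cj, rj in _residue_contacts(state):
        if ci == cj and abs(ri - rj) > 1:
            if (min(ri, rj), max(ri, rj)) in state.chains[ci].native_pairs:
                n += 1
    n_max = sum(len(c.native_pairs) for c in state.chains)
    return n / max(1, n_max)


def _wall_faces(state: LatticeState) -> int:
    L = state.L
    return int(
        np.sum(state.hydro[:, 0] != 0) + np.sum(state.hydro[:, L - 1] != 0)
    )


def compute_Ic(state: LatticeState) -> float:
    """Inter-chain contacts plus wall contacts, normalized by 36 Np."""
    n = sum(1 for ci, _, cj, _ in _residue_contacts(state) if ci != cj)
    n += _wall_faces(state)
    return n / max(1, sum(len(c) for c in state.chains))


def compute_Mc(state: LatticeState) -> float:
    """Residue faces on either wall, normalized by 2L."""
    return _wall_faces(state) / (2 * state.L)


# --------------------------------------------------------------------------
# free-energy profiles
# --------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """Binned probability and ``F* = -T* ln P``, min-shifted to zero."""

    bins: np.ndarray       # observable value at each occupied bin
    counts: np.ndarray     # samples per occupied bin
    P: np.ndarray          # relative frequency (sums to 1)
    F_star: np.ndarray     # -T* ln P, min-shifted
    T_star: float
    bin_width: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bins, "count": self.counts, "P": self.P, "F_star": self.F_star}
        )


def free_energy_profile(
    samples, T_star: float, bin_width: float
) -> FreeEnergyProfile:
    """Histogram ``samples`` on natural bins and convert to free energy.

    ``bin_width`` should be the observable's quantum (e.g. ``1/(25*Np)`` for
    Nc) so every attainable value maps to its own bin.  Bins with zero count
    carry no F value and are omitted.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample sequence")
    k = np.rint(samples / bin_width).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)
    P = counts / counts.sum()
    F = -T_star * np.log(P)
    return FreeEnergyProfile(
        bins=uniq * bin_width,
        counts=counts,
        P=P,
        F_star=F - F.min(),
        T_star=T_star,
        bin_width=bin_width,
    )


def free_energy_surface(
    nc_samples, ic_samples, T_star: float, n_proteins: int, nc_quantum: float | None = None
) -> pd.DataFrame:
    """2D free-energy surface over (Nc as percentage, 25 Np x Ic).

    Long-format table with columns ``Nc_pct``, ``inter25Np``, ``count``,
    ``F_star`` (min-shifted, occupied cells only); axis conventions follow
    the standard presentation of folding-aggregation landscapes.
    """
    nc = np.asarray(nc_samples, dtype=float)
    ic = np.asarray(ic_samples, dtype=float)
    if nc.shape != ic.shape:
        raise ValueError("sample sequences differ in length")
    if nc.size == 0:
        raise ValueError("empty sample sequences")
    qn = 1.0 / (25 * n_proteins) if nc_quantum is None else nc_quantum
    kn = np.rint(nc / qn).astype(np.int64)
    # Ic quantum 1/(36 Np); the axis is scaled to 25 Np * Ic
    qi = 1.0 / (36 * n_proteins)
    ki = np.rint(ic / qi).astype(np.int64)
    keys, counts = np.unique(np.stack([kn, ki], axis=1), axis=0, return_counts=True)
    P = counts / counts.sum()
    F = -T_star * np.log(P)
    return pd.DataFrame(
        {
            "Nc_pct": keys[:, 0] * qn * 100.0,
            "inter25Np": keys[:, 1] * qi * 25 * n_proteins,
            "count": counts,
            "F_star": F - F.min(),
        }
    )


def find_minimum(
    profile: FreeEnergyProfile, min_count: int = 10, tie_break: str = "upper"
) -> float:
    """Location of the global minimum of ``F*`` among well-sampled bins.

    Only bins with at least ``min_count`` samples compete, so single-visit
    outliers cannot masquerade as minima.  Exact ties go to the larger bin
    value when ``tie_break="upper"`` (folded side for Nc) and to the smaller
    when ``"lower"`` (unaggregated side for Ic/Mc).
    """
    mask = profile.counts >= min_count
    if not np.any(mask):
        raise ValueError(f"no bin has at least {min_count} samples")
    bins = profile.bins[mask]
    F = profile.F_star[mask]
    best = F.min()
    cand = bins[np.isclose(F, best)]
    return float(cand.max() if tie_break == "upper" else cand.min())
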