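"""Metropolis Monte Carlo at constant temperature and pressure.

One MC step consists of (i) ``Np`` attempts of one randomly drawn global
protein move (shift, rotation, crankshaft or pivot, each on a uniformly
chosen chain, drawn with replacement), (ii) ``m ~ U[1, 4L^2]`` local
attempts -- a corner flip when the drawn cell holds a residue, a bonding
variable flip when it holds water -- and (iii) one global volume move.
Every proposal kernel is symmetric, so plain Metropolis acceptance
``min(1, exp(-(dH + P dV)/kBT))`` satisfies detailed balance; infeasible
proposals (overlap with residues or walls, no bend at the drawn cell) are
outright rejections that leave the state bit-identical.

:class:`Simulation` owns the packed array state consumed by the numba
kernels and exposes single-move entry points (used heavily by the tests),
the step/run loop, bookkeeping audits against the reference
:mod:`hydrofold.energetics`, and equilibration detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .energetics import EnergyBreakdown, VolumeBreakdown, total_enthalpy, total_volume
from .lattice import LatticeState
from .parameters import ModelParameters
from .protein import load_mj_matrix

__all__ = ["MoveOutcome", "RunConfig", "Simulation", "detect_equilibration", "MOVE_KINDS"]

MOVE_KINDS = ("shift", "rotation", "crankshaft", "pivot", "corner", "sigma", "volume")

RECORD_COLUMNS = (
    "step", "Nc", "Ic", "Mc",
    "NHB_b", "NHB_phi", "NHB_zeta", "NHB_chi",
    "enthalpy", "volume", "v_rel",
)


@dataclass(frozen=True)
class MoveOutcome:
    """Result of a single attempted move."""

    move_kind: str
    accepted: bool
    dH: float
    dV: float


@dataclass
class RunConfig:
    """Driver settings for a production or equilibration run."""

    n_steps: int
    record_stride: int = 1
    equil_window: int = 200          # records, for drift detection
    drift_tolerance: float = 3.0     # |slope| < tol * s.e. counts as no drift

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.record_stride < 1:
            raise ValueError("n_steps and record_stride must be >= 1")


class Simulation:
    """Monte Carlo engine bound to one :class:`LatticeState`.

    The lattice grids (occupancy, bonding variables) are shared with the
    ``state`` object and mutated in place; chain coordinates and the cell
    volume are synchronised back on :attr:`state` access.
    """

    def __init__(
        self,
        state: LatticeState,
        params: ModelParameters,
        matrix: np.ndarray | None = None,
        seed: int = 0,
        delta_max: float = 0.05,
        volume_moves: bool = True,
        protein_moves: bool = True,
    ) -> None:
        self.params = params
        self._state = state
        self.matrix = load_mj_matrix() if matrix is None else np.asarray(matrix, float)
        L = state.L
        Np = max(1, state.n_proteins)
        nmax = max([len(c) for c in state.chains], default=1)

        self.cx = np.zeros((Np, nmax), dtype=np.int64)
        self.cy = np.zeros((Np, nmax), dtype=np.int64)
        self.clen = np.zeros(Np, dtype=np.int64)
        self.aa = np.zeros((Np, nmax), dtype=np.int8)
        self.hyd_seq = np.zeros((Np, nmax), dtype=np.int8)
        for i, c in enumerate(state.chains):
            n = len(c)
            self.clen[i] = n
            self.cx[i, :n] = c.coords[:, 0]
            self.cy[i, :n] = c.coords[:, 1]
            self.aa[i, :n] = c.sequence.aa_indices
            self.hyd_seq[i, :n] = c.sequence.hydropathy

        maps = [c.native_pairs for c in state.chains]
        self.native = np.zeros((nmax, nmax), dtype=np.bool_)
        if maps and all(m == maps[0] for m in maps):
            for i, j in maps[0]:
                self.native[i, j] = True
                self.native[j, i] = True
        self.n_native = int(self.native.sum() // 2)

        p = params
        self.jhb = np.array([p.J, p.J_phi, p.J_zeta, p.J_chi])
        self.jco = np.array([p.Jsig, p.Jsig_phi, p.Jsig_zeta, p.Jsig_chi])
        self.vhb = np.array([p.vHB_b, p.vHB_phi(), p.vHB_zeta, p.vHB_chi()])
        self.epw = np.array([0.0, p.eps_phi, p.eps_zeta])

        self.counts = np.zeros(10, dtype=np.int64)
        self.pair_hist = np.zeros(K.MAX_D2 + 1, dtype=np.int64)
        self.u_tab = np.zeros(K.MAX_D2 + 1, dtype=np.float64)
        self.fstate = np.array(
            [state.v, 0.0, p.T_star, p.P_star, delta_max, p.n_threshold]
        )
        ni = 1 if state.v / p.v0 < p.n_threshold else 0
        self.istate = np.array(
            [L, state.n_proteins, p.q, ni, 0, 0, 1 if volume_moves else 0, nmax,
             1 if protein_moves else 0],
            dtype=np.int64,
        )
        self.acc = np.zeros((7, 2), dtype=np.int64)

        # workspace
        self._stamp = np.zeros((L, L), dtype=np.int64)
        self._stamp2 = np.zeros((L, L), dtype=np.int64)
        cap = 16 * (nmax + 4)
        self._regx = np.zeros(cap, dtype=np.int64)
        self._regy = np.zeros(cap, dtype=np.int64)
        self._moved = np.zeros(nmax, dtype=np.int8)
        self._sx = np.zeros(nmax, dtype=np.int64)
        self._sy = np.zeros(nmax, dtype=np.int64)
        self._remx = np.zeros(nmax, dtype=np.int64)
        self._remy = np.zeros(nmax, dtype=np.int64)
        self._addx = np.zeros(nmax, dtype=np.int64)
        self._addy = np.zeros(nmax, dtype=np.int64)
        self._idx = np.zeros(nmax, dtype=np.int64)
        self._px = np.zeros(nmax, dtype=np.int64)
        self._py = np.zeros(nmax, dtype=np.int64)
        self._buf_a = np.zeros(10, dtype=np.int64)
        self._buf_b = np.zeros(10, dtype=np.int64)

        self.labels = np.zeros((L, L), dtype=np.int8)
        self.G = (state.hydro, state.occ_chain, state.occ_res, state.sigma, self.labels)
        self.C = (self.cx, self.cy, self.clen, self.aa, self.hyd_seq, self.native)
        self.E = (
            self.matrix, self.counts, self.pair_hist, self.u_tab,
            self.jhb, self.jco, self.vhb, self.epw,
        )
        self.W = (
            self.fstate, self.istate, self._stamp, self._stamp2,
            self._regx, self._regy, self._moved, self._sx, self._sy,
            self._remx, self._remy, self._addx, self._addy, self.acc,
        )

        K.build_u_tab(self.u_tab, self.fstate[K.IF_V])
        K.full_recount(self.G, self.C, self.E, self.W)
        self.reseed(seed)

    # -- RNG ---------------------------------------------------------------
    def reseed(self, seed: int) -> None:
        """Seed the kernel RNG (one stream per process)."""
        K.seed_kernel(int(seed))

    # -- move-set control ----------------------------------------------------
    def set_protein_moves(self, enabled: bool) -> None:
        """Enable/disable all conformational moves (sigma/volume still run)."""
        self.istate[K.II_PROT] = 1 if enabled else 0

    def anneal_water(self, n_steps: int) -> None:
        """Equilibrate water (bonding variables, volume) at frozen conformations.

        Native placements start against uncorrelated high-T bonding variables;
        annealing first avoids conformational moves being judged against
        unequilibrated hydration water.
        """
        prev = int(self.istate[K.II_PROT])
        self.istate[K.II_PROT] = 0
        self.step(n_steps)
        self.istate[K.II_PROT] = prev

    # -- state synchronisation ---------------------------------------------
    @property
    def state(self) -> LatticeState:
        """The lattice state, with chain coordinates synchronised back."""
        st = self._state
        st.v = float(self.fstate[K.IF_V])
        for i, c in enumerate(st.chains):
            n = len(c)
            c.coords[:, 0] = self.cx[i, :n]
            c.coords[:, 1] = self.cy[i, :n]
        return st

    # -- normalisations -----------------------------------------------------
    @property
    def nc_max(self) -> int:
        return max(1, self.n_native * self._state.n_proteins)

    @property
    def ic_max(self) -> int:
        return max(1, sum(len(c) for c in self._state.chains))

    @property
    def mc_max(self) -> int:
        return 2 * self._state.L

    # -- single moves (symmetric proposals + Metropolis) --------------------
    def attempt_global_move(self, kind: str, chain: int) -> MoveOutcome:
        k = MOVE_KINDS.index(kind)
        if k > 3:
            raise ValueError(f"{kind!r} is not a global protein move")
        nm = K.propose_global(self.C, self.W, k, chain, self._idx, self._px, self._py)
        if nm == 0:
            self.acc[k, 0] += 1
            return MoveOutcome(kind, False, 0.0, 0.0)
        ok, dh, dv = K.attempt_chain_move(
            self.G, self.C, self.E, self.W, k, chain, self._idx, nm,
            self._px, self._py, self._buf_a, self._buf_b,
        )
        return MoveOutcome(kind, bool(ok), dh, dv)

    def attempt_corner_flip(self, cell: tuple[int, int]) -> MoveOutcome:
        x, y = cell[0] % self._state.L, cell[1]
        if self._state.hydro[x, y] == 0:
            raise ValueError("corner flip requires a residue cell")
        nm, ci = K.propose_corner(self.G, self.C, self.W, x, y, self._idx, self._px, self._py)
        if nm == 0:
            self.acc[K.K_CORNER, 0] += 1
            return MoveOutcome("corner", False, 0.0, 0.0)
        ok, dh, dv = K.attempt_chain_move(
            self.G, self.C, self.E, self.W, K.K_CORNER, ci, self._idx, nm,
            self._px, self._py, self._buf_a, self._buf_b,
        )
        return MoveOutcome("corner", bool(ok), dh, dv)

    def attempt_sigma_flip(
        self, cell: tuple[int, int], direction: int, new_value: int | None = None
    ) -> MoveOutcome:
        x, y = cell[0] % self._state.L, cell[1]
        if self._state.hydro[x, y] != 0:
            raise ValueError("sigma flip requires a water cell")
        ok, dh, dv = K.attempt_sigma_flip(
            self.G, self.C, self.E, self.W, x, y, int(direction),
            0 if new_value is None else int(new_value),
        )
        return MoveOutcome("sigma", bool(ok), dh, dv)

    def attempt_volume_move(self, dv: float | None = None) -> MoveOutcome:
        ok, dh, dvol = K.attempt_volume_move(
            self.G, self.C, self.E, self.W, np.nan if dv is None else float(dv)
        )
        return MoveOutcome("volume", bool(ok), dh, dvol)

    # -- stepping ------------------------------------------------------------
    def step(self, n: int = 1) -> None:
        for _ in range(n):
            K.mc_step(
                self.G, self.C, self.E, self.W,
                self._idx, self._px, self._py, self._buf_a, self._buf_b,
            )

    def run(self, n_steps: int, record_stride: int = 1, step0: int = 0) -> pd.DataFrame:
        """Advance ``n_steps`` and return the recorded observable series.

        Recording has no side effects on the dynamics: the trajectory is
        identical for any stride.
        """
        n_rec = n_steps // record_stride
        rec = np.zeros((n_rec, 11), dtype=np.float64)
        got = K.run_steps(
            self.G, self.C, self.E, self.W,
            self._idx, self._px, self._py, self._buf_a, self._buf_b,
            n_steps, record_stride, step0, rec,
        )
        rec = rec[:got]
        df = pd.DataFrame(rec, columns=list(RECORD_COLUMNS))
        df["step"] = df["step"].astype(np.int64)
        df["Nc"] = rec[:, 1] / self.nc_max
        df["Ic"] = rec[:, 2] / self.ic_max
        df["Mc"] = rec[:, 3] / self.mc_max
        return df

    # -- derived quantities ---------------------------------------------------
    def observables(self) -> tuple[float, float, float]:
        """Current (Nc, Ic, Mc) fractions."""
        nat, ic, mc = K.count_observables(self.G, self.C, self.W)
        return nat / self.nc_max, ic / self.ic_max, mc / self.mc_max

    def total_enthalpy(self) -> float:
        return float(K.total_energy(self.E, self.W))

    def total_volume(self) -> float:
        return float(K.total_volume_k(self.E, self.W))

    def nhb_counts(self) -> np.ndarray:
        """ni-weighted HB counts per class [bulk, phi, zeta, chi]."""
        return self.istate[K.II_NI] * self.counts[:4].copy()

    def ncoop_counts(self) -> np.ndarray:
        return self.istate[K.II_NI] * self.counts[4:8].copy()

    def acceptance_rates(self) -> dict[str, float]:
        out = {}
        for i, name in enumerate(MOVE_KINDS):
            att, acc = self.acc[i]
            out[name] = float(acc) / float(att) if att else float("nan")
        return out

    # -- audits ----------------------------------------------------------------
    def verify_bookkeeping(self) -> float:
        """Compare bookkept counts/energies against full reference recomputation.

        Returns the largest relative deviation found (0.0 for exact integer
        agreement); raises AssertionError on any integer mismatch.
        """
        st = self.state
        ref_e = total_enthalpy(st, self.params, self.matrix)
        ref_v = total_volume(st, self.params)
        ni = self.istate[K.II_NI]
        assert np.array_equal(ni * self.counts[:4], ref_e.NHB), "HB count mismatch"
        assert np.array_equal(ni * self.counts[4:8], ref_e.Ncoop), "coop count mismatch"
        dev = 0.0
        for mine, ref in (
            (self.total_enthalpy(), ref_e.total),
            (float(self.fstate[K.IF_EMJ]), ref_e.E_mj),
            (self.total_volume(), ref_v.total),
        ):
            scale = max(1.0, abs(ref))
            dev = max(dev, abs(mine - ref) / scale)
        return dev

    def energy_breakdown(self) -> EnergyBreakdown:
        """Reference-grade breakdown of the current state's enthalpy."""
        return total_enthalpy(self.state, self.params, self.matrix)

    def volume_breakdown(self) -> VolumeBreakdown:
        return total_volume(self.state, self.params)


# --------------------------------------------------------------------------
# equilibration detection
# --------------------------------------------------------------------------

def detect_equilibration(
    records: pd.DataFrame,
    window: int,
    tolerance: float = 3.0,
    columns: tuple[str, ...] = ("Nc", "Ic", "Mc"),
) -> int | None:
    """Earliest recorded step after which all observables stop drifting.

    Scans windows of ``window`` consecutive records; a window qualifies when
    the fitted linear slope of every column is statistically indistinguishable
    from zero (``|slope| < tolerance * s.e.``, with exactly-constant series
    passing trivially).  Returns the step of the first record of the first
    qualifying window, or None.
    """
    n = len(records)
    if window > n:
        raise ValueError(f"window ({window}) longer than the series ({n})")
    x = np.arange(window, dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    for start in range(0, n - window + 1):
        ok = True
        for col in columns:
            ys = records[col].to_numpy()[start : start + window]
            slope = float(np.sum((x - x.mean()) * (ys - ys.mean())) / sxx)
            resid = ys - ys.mean() - slope * (x - x.mean())
            dof = max(window - 2, 1)
            se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
            if slope != 0.0 and not (abs(slope) < tolerance * se):
                ok = False
                break
        if ok:
            return int(records["step"].iloc[start])
    return None
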