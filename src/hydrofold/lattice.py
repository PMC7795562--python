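"""Confined L x L lattice state: occupancy, bonding variables, walls.

Geometry conventions (fixed throughout the package):

* coordinates are 0-based; ``x`` is the periodic axis, ``y`` the confined one;
* two hydrophobic walls sit just outside rows ``y = 0`` and ``y = L-1`` (the
  system is an infinite slab between parallel walls at distance L);
* every cell holds either one water molecule or one protein residue;
* each cell carries four bonding variables ``sigma`` in ``1..q``, indexed by
  direction ``0:+x, 1:-x, 2:+y, 3:-y``.  They are attached to cells and stay
  latent under residue occupancy, so protein moves never create or destroy
  bonding degrees of freedom;
* one global volume per cell ``v >= v0`` sets the NN spacing ``r = sqrt(v/h)``.

Water cells are classified by adjacency into hydration-shell classes: bulk
(no residue or wall nearby), phi (hydrophobic residues and/or walls), zeta
(hydrophilic residues only) and chi (mixed).  Walls count as hydrophobic
neighbours for this labeling but are purely excluded volume otherwise: they
never accept hydrogen bonds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .protein import (
    Sequence,
    build_rod,
    build_snake_native,
    default_snake_sequence,
    is_valid_conformation,
    native_contact_map,
)

__all__ = [
    "BULK",
    "PHI",
    "ZETA",
    "CHI",
    "WATER",
    "ProteinChain",
    "LatticeState",
    "init_state",
    "classify_water",
    "classify_hb_pair",
    "save_snapshot",
    "load_snapshot",
]

# shell labels
BULK, PHI, ZETA, CHI = 0, 1, 2, 3
#: occupancy marker for water in the hydropathy grid
WATER = 0

SHELL_NAMES = {BULK: "bulk", PHI: "phi", ZETA: "zeta", CHI: "chi"}

DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class ProteinChain:
    """One self-avoiding chain: unwrapped coordinates plus its sequence.

    ``coords[:, 0]`` (x) may run outside ``[0, L)``; the wrapped position is
    ``x % L``.  ``coords[:, 1]`` (y) must stay inside the slab.
    """

    coords: np.ndarray
    sequence: Sequence
    native_pairs: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).copy()
        if len(self.coords) != len(self.sequence):
            raise ValueError("chain length does not match sequence length")
        if self.native_pairs is None:
            side = int(round(np.sqrt(len(self.coords))))
            if side * side == len(self.coords):
                self.native_pairs = native_contact_map(build_snake_native(len(self.coords)))
            else:
                self.native_pairs = frozenset()

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class LatticeState:
    """Full microstate of the confined system."""

    L: int
    v: float
    chains: list[ProteinChain]
    sigma: np.ndarray  # (L, L, 4) int8, values 1..q
    hydro: np.ndarray = field(default=None)  # type: ignore[assignment]
    occ_chain: np.ndarray = field(default=None)  # type: ignore[assignment]
    occ_res: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int8)
        if self.sigma.shape != (self.L, self.L, 4):
            raise ValueError("sigma must have shape (L, L, 4)")
        self.rebuild_occupancy()

    # -- derived grids ------------------------------------------------------
    def rebuild_occupancy(self) -> None:
        """Recompute the occupancy/hydropathy grids from the chain list."""
        L = self.L
        self.hydro = np.zeros((L, L), dtype=np.int8)
        self.occ_chain = np.full((L, L), -1, dtype=np.int16)
        self.occ_res = np.full((L, L), -1, dtype=np.int16)
        for ci, chain in enumerate(self.chains):
            if not is_valid_conformation(chain.coords):
                raise ValueError(f"chain {ci} is not a valid self-avoiding chain")
            hyd = chain.sequence.hydropathy
            for ri, (x, y) in enumerate(chain.coords):
                if not (0 <= y < L):
                    raise ValueError(f"chain {ci} residue {ri} outside the slab (y={y})")
                xw = int(x) % L
                if self.occ_chain[xw, y] != -1:
                    raise ValueError(f"residue overlap at cell ({xw}, {y})")
                self.occ_chain[xw, y] = ci
                self.occ_res[xw, y] = ri
                self.hydro[xw, y] = hyd[ri]

    @property
    def n_proteins(self) -> int:
        return len(self.chains)

    @property
    def n_water(self) -> int:
        return int(np.sum(self.hydro == WATER))

    def is_water(self, x: int, y: int) -> bool:
        return self.hydro[x % self.L, y] == WATER

    def copy(self) -> "LatticeState":
        return LatticeState(
            L=self.L,
            v=self.v,
            chains=[
                ProteinChain(c.coords.copy(), c.sequence, c.native_pairs)
                for c in self.chains
            ],
            sigma=self.sigma.copy(),
        )


# --------------------------------------------------------------------------
# shell classification
# --------------------------------------------------------------------------

def classify_water(state: LatticeState, cell: tuple[int, int]) -> int:
    """Hydration-shell label of a water cell from its four NN cells.

    phi if adjacent to at least one hydrophobic residue or a wall and to no
    hydrophilic residue; zeta in the mirrored case; chi if adjacent to both
    kinds; bulk otherwise.  Pure function of the occupancy neighbourhood.
    """
    x, y = cell
    L = state.L
    x %= L
    if state.hydro[x, y] != WATER:
        raise ValueError(f"cell ({x}, {y}) does not hold water")
    phi = zeta = False
    for dx, dy in DIRS:
        ny = y + dy
        if ny < 0 or ny >= L:
            phi = True  # wall counts as hydrophobic neighbour
            continue
        h = state.hydro[(x + dx) % L, ny]
        if h == 1:
            phi = True
        elif h == 2:
            zeta = True
    if phi and zeta:
        return CHI
    if phi:
        return PHI
    if zeta:
        return ZETA
    return BULK


def classify_hb_pair(
    state: LatticeState, cell_i: tuple[int, int], cell_j: tuple[int, int]
) -> int:
    """Class of a hydrogen bond between two NN water cells.

    Bulk if either endpoint is bulk water; phi/zeta if both endpoints share
    that label; chi for a phi-zeta pair or any chi endpoint.
    """
    L = state.L
    xi, yi = cell_i[0] % L, cell_i[1]
    xj, yj = cell_j[0] % L, cell_j[1]
    dx = (xi - xj) % L
    if not ((min(dx, L - dx) == 1 and yi == yj) or (dx == 0 and abs(yi - yj) == 1)):
        raise ValueError("cells are not nearest neighbours")
    la = classify_water(state, (xi, yi))
    lb = classify_water(state, (xj, yj))
    if la == BULK or lb == BULK:
        return BULK
    if la == lb:
        return la
    return CHI


# --------------------------------------------------------------------------
# initial states
# --------------------------------------------------------------------------

def _grid_layout(L: int, n: int, side_x: int, side_y: int) -> list[tuple[int, int]]:
    """Homogeneous, non-overlapping anchor points for ``n`` footprints.

    Footprints of ``side_x x side_y`` cells are laid out on a grid, centred
    columns along the periodic axis and rows kept off the wall rows.  Raises
    when no grid fits.
    """
    if n == 0:
        return []
    best = int(np.ceil(np.sqrt(n)))
    candidates = list(range(best, 0, -1)) + list(range(best + 1, n + 1))
    for ncols in candidates:
        if L // ncols < side_x:
            continue
        nrows = int(np.ceil(n / ncols))
        if nrows * side_y > L - 2:
            continue
        # centred row positions; fall back to maximal spread if too tight
        if nrows == 1:
            ys = [(L - side_y) // 2]
        else:
            ys = [int(round((L - side_y) * (r + 1) / (nrows + 1))) for r in range(nrows)]
            if min(np.diff(ys)) < side_y or ys[0] < 1 or ys[-1] > L - 1 - side_y:
                step = (L - 2 - side_y) / (nrows - 1)
                if step < side_y:
                    continue
                ys = [int(round(1 + r * step)) for r in range(nrows)]
        anchors = []
        for k in range(n):
            row, col = divmod(k, ncols)
            x0 = int(round(col * L / ncols + (L / ncols - side_x) / 2)) % L
            anchors.append((x0, ys[row]))
        return anchors
    raise ValueError(f"cannot place {n} proteins of footprint {side_x}x{side_y} on L={L}")


def init_state(
    params,
    L: int,
    n_proteins: int,
    seed: int,
    *,
    start: str = "extended",
    v_init: float | None = None,
    sequence: Sequence | None = None,
    n_residues: int = 36,
) -> LatticeState:
    """Build a deterministic initial state.

    ``start="extended"`` places straight rods on a homogeneous grid (the
    high-temperature start used for equilibration from scratch);
    ``start="native"`` places compact native squares away from the walls,
    the short-equilibration start for folded-regime runs.  Bonding variables
    are uniform random in ``1..q`` (a high-T water configuration); the cell
    volume defaults to ``1.2*v0``, near the LJ minimum.
    """
    if n_residues * n_proteins >= L * L:
        raise ValueError("proteins do not fit on the lattice")
    rng = np.random.default_rng(seed)
    seq = sequence if sequence is not None else (
        default_snake_sequence() if n_residues == 36 else None
    )
    if seq is None:
        raise ValueError("a sequence must be supplied for non-36-residue proteins")

    chains: list[ProteinChain] = []
    if n_proteins == 0:
        pass
    elif start == "extended":
        if n_residues > L:
            raise ValueError("extended rods longer than L would self-overlap under PBC")
        base = build_rod(n_residues)
        anchors = _grid_layout(L, n_proteins, min(n_residues, L), 1)
        for x0, y0 in anchors:
            coords = base.copy()
            coords[:, 0] += x0
            coords[:, 1] += y0
            chains.append(ProteinChain(coords, seq))
    elif start == "native":
        side = int(round(np.sqrt(n_residues)))
        base = build_snake_native(n_residues)
        anchors = _grid_layout(L, n_proteins, side, side)
        for x0, y0 in anchors:
            coords = base.copy()
            coords[:, 0] += x0
            coords[:, 1] += y0
            chains.append(ProteinChain(coords, seq))
    else:
        raise ValueError(f"unknown start {start!r}")

    sigma = rng.integers(1, params.q + 1, size=(L, L, 4), endpoint=False).astype(np.int8)
    state = LatticeState(
        L=L, v=float(v_init) if v_init is not None else 1.2, chains=chains, sigma=sigma
    )
    # placement sanity: grid construction raises on overlap / wall contact
    if np.any(state.hydro[:, 0] != WATER) or np.any(state.hydro[:, L - 1] != WATER):
        raise ValueError("initial placement touches a wall row")
    return state


# --------------------------------------------------------------------------
# snapshots (plain text, lossless round-trip)
# --------------------------------------------------------------------------

def save_snapshot(state: LatticeState, path=None, header: dict | None = None) -> str:
    """Serialize a state to plain text; returns the text, optionally writes it.

    Layout: a key=value header line, one line per residue
    ``chain residue x y aa hydropathy`` (x unwrapped), then one line per cell
    ``x y s+x s-x s+y s-y``.  Round-trips losslessly through
    :func:`load_snapshot`.
    """
    buf = io.StringIO()
    meta = {"L": state.L, "v": repr(float(state.v)), "Np": state.n_proteins}
    if header:
        meta.update(header)
    buf.write("# hydrofold snapshot\n")
    buf.write(" ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
    buf.write("# chain residue x y aa hydropathy\n")
    for ci, chain in enumerate(state.chains):
        hyd = chain.sequence.hydropathy
        for ri, (x, y) in enumerate(chain.coords):
            lab = "phi" if hyd[ri] == 1 else "zeta"
            buf.write(f"C {ci} {ri} {x} {y} {chain.sequence.residues[ri]} {lab}\n")
    buf.write("# x y sigma(+x) sigma(-x) sigma(+y) sigma(-y)\n")
    for x in range(state.L):
        for y in range(state.L):
            s = state.sigma[x, y]
            buf.write(f"S {x} {y} {s[0]} {s[1]} {s[2]} {s[3]}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def load_snapshot(source) -> tuple[LatticeState, dict]:
    """Inverse of :func:`save_snapshot`; accepts a path or the text itself."""
    if isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as f:
            text = f.read()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    meta = dict(kv.split("=", 1) for kv in lines[0].split())
    L = int(meta["L"])
    v = float(meta["v"])
    chain_rows: dict[int, list[tuple[int, int, int, str]]] = {}
    sigma = np.zeros((L, L, 4), dtype=np.int8)
    for ln in lines[1:]:
        parts = ln.split()
        if parts[0] == "C":
            ci, ri, x, y = (int(p) for p in parts[1:5])
            chain_rows.setdefault(ci, []).append((ri, x, y, parts[5]))
        elif parts[0] == "S":
            x, y = int(parts[1]), int(parts[2])
            sigma[x, y] = [int(p) for p in parts[3:7]]
    chains = []
    for ci in sorted(chain_rows):
        rows = sorted(chain_rows[ci])
        coords = np.array([(x, y) for _, x, y, _ in rows], dtype=np.int64)
        seq = Sequence("".join(aa for _, _, _, aa in rows))
        chains.append(ProteinChain(coords, seq))
    return LatticeState(L=L, v=v, chains=chains, sigma=sigma), meta
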