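"""Named deterministic micro-states with oracle-computed expectations.

Each fixture is a small, fully specified :class:`LatticeState` together with
the exact quantities the test-suite checks against.  Every expectation is
*computed* at generation time -- by the enumeration oracle for thermal
averages, by the reference observable functions for geometric counts --
never hand-entered.

The two-water fixtures freeze all protein degrees of freedom by paving the
lattice with immobile chains (straight rods and L-shaped paths admit no
corner flips into the remaining water cells and no global move has room),
leaving only the eight bonding variables of the two water cells dynamic:
a two-molecule system embedded in the genuine simulation machinery.  With
hydrophilic paving the waters sit in a zeta shell, whose couplings equal the
bulk ones, so the textbook isolated-pair HB statistics apply literally; with
hydrophobic paving on the wall row they form a phi-shell pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeState, ProteinChain
from .observables import compute_Ic, compute_Mc, compute_Nc
from .oracle import enumerate_exact
from .parameters import ModelParameters, make_parameters
from .protein import Sequence, build_snake_native, default_snake_sequence

__all__ = ["Fixture", "generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "two-waters",
    "two-waters-wall",
    "native-snake-L12",
    "two-snakes-touching",
    "wall-flush-snake",
)


@dataclass
class Fixture:
    name: str
    state: LatticeState
    params: ModelParameters
    expected: dict = field(default_factory=dict)


def _paved_two_waters(wall: bool, params: ModelParameters, seed: int) -> LatticeState:
    """L=4 lattice, every cell but two NN waters occupied by frozen chains."""
    L = 4
    if wall:
        # waters on the wall row, hydrophobic paving -> phi-shell pair
        aa = "L"
        chains = [
            ProteinChain(
                np.array([(0, 0), (0, 1), (1, 1), (2, 1), (3, 1), (3, 0)]), Sequence(aa * 6)
            ),
            ProteinChain(np.array([(x, 2) for x in range(4)]), Sequence(aa * 4)),
            ProteinChain(np.array([(x, 3) for x in range(4)]), Sequence(aa * 4)),
        ]
        waters = [(1, 0), (2, 0)]
    else:
        # waters mid-slab, hydrophilic paving -> zeta shell == bulk couplings
        aa = "S"
        chains = [
            ProteinChain(np.array([(x, 0) for x in range(4)]), Sequence(aa * 4)),
            ProteinChain(
                np.array([(0, 1), (1, 1), (2, 1), (3, 1), (3, 2), (4, 2)]), Sequence(aa * 6)
            ),
            ProteinChain(np.array([(x, 3) for x in range(4)]), Sequence(aa * 4)),
        ]
        waters = [(1, 2), (2, 2)]
    rng = np.random.default_rng(seed)
    sigma = rng.integers(1, params.q + 1, size=(L, L, 4)).astype(np.int8)
    state = LatticeState(L=L, v=1.2, chains=chains, sigma=sigma)
    for w in waters:
        assert state.hydro[w] == 0, "fixture paving error"
    assert state.n_water == 2
    return state


def _snake_state(
    L: int, anchors: list[tuple[int, int]], params: ModelParameters, seed: int
) -> LatticeState:
    base = build_snake_native(36)
    seq = default_snake_sequence()
    chains = []
    for x0, y0 in anchors:
        coords = base.copy()
        coords[:, 0] += x0
        coords[:, 1] += y0
        chains.append(ProteinChain(coords, seq))
    rng = np.random.default_rng(seed)
    sigma = rng.integers(1, params.q + 1, size=(L, L, 4)).astype(np.int8)
    return LatticeState(L=L, v=1.2, chains=chains, sigma=sigma)


def generate_fixture(
    name: str, seed: int = 0, scale_id: int = 0, T_star: float = 0.4, P_star: float = 0.0
) -> Fixture:
    """Build a named fixture; deterministic for a given seed."""
    params = make_parameters(scale_id, T_star, P_star)
    if name == "two-waters":
        state = _paved_two_waters(False, params, seed)
        expected = enumerate_exact(state, params)
    elif name == "two-waters-wall":
        state = _paved_two_waters(True, params, seed)
        expected = enumerate_exact(state, params)
    elif name == "native-snake-L12":
        state = _snake_state(12, [(3, 3)], params, seed)
        expected = {
            "Nc": compute_Nc(state), "Ic": compute_Ic(state), "Mc": compute_Mc(state)
        }
    elif name == "two-snakes-touching":
        state = _snake_state(16, [(2, 5), (8, 5)], params, seed)
        expected = {
            "Nc": compute_Nc(state), "Ic": compute_Ic(state), "Mc": compute_Mc(state)
        }
    elif name == "wall-flush-snake":
        state = _snake_state(12, [(3, 0)], params, seed)
        expected = {
            "Nc": compute_Nc(state), "Ic": compute_Ic(state), "Mc": compute_Mc(state)
        }
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return Fixture(name=name, state=state, params=params, expected=expected)
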