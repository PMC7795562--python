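import numpy as np
import pytest

import hydrofold as hf
from hydrofold.montecarlo import Simulation


@pytest.fixture(scope="session")
def mj():
    return hf.load_mj_matrix()


@pytest.fixture(scope="session")
def params04():
    """Scale 0 at the warmer temperature, ambient pressure."""
    return hf.make_parameters(0, 0.4, 0.0)


@pytest.fixture()
def small_sim(params04, mj):
    """Two native snakes on L=12 (dense, plenty of residue-water interface)."""
    state = hf.init_state(params04, 12, 2, seed=5, start="native")
    return Simulation(state, params04, matrix=mj, seed=5)


def state_digest(sim: Simulation) -> tuple:
    """Hashable digest of the complete microstate (for bit-identity checks)."""
    st = sim._state
    return (
        st.hydro.tobytes(),
        st.occ_chain.tobytes(),
        st.occ_res.tobytes(),
        st.sigma.tobytes(),
        sim.cx.tobytes(),
        sim.cy.tobytes(),
        sim.counts.tobytes(),
        sim.pair_hist.tobytes(),
        float(sim.fstate[0]),
        float(sim.fstate[1]),
    )


def block_se(x, nblocks=25):
    """Standard error from block averages (handles autocorrelation crudely)."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // nblocks) * nblocks
    b = x[:n].reshape(nblocks, -1).mean(axis=1)
    return b.std(ddof=1) / np.sqrt(nblocks)
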