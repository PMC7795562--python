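"""Parameters, lattice state construction, shell classification, snapshots."""

import numpy as np
import pytest

import hydrofold as hf
from hydrofold.lattice import BULK, CHI, PHI, ZETA, ProteinChain
from hydrofold.protein import Sequence


class TestParameters:
    def test_scale0_table_conversion(self):
        p = hf.make_parameters(0, 0.3, 0.0)
        assert p.J == pytest.approx(0.3 * 8)
        assert p.J_phi == pytest.approx(1.2 * 8)
        assert p.eps_phi == pytest.approx(0.48 * 8)
        assert p.vHB0_phi == pytest.approx(2.0)
        assert p.k1 == pytest.approx(4.0)
        assert p.eps_zeta == 0.0

    def test_derived_mixed_couplings(self):
        p1 = hf.make_parameters(1, 0.3, 0.0)
        assert p1.J_chi == pytest.approx(0.5 * (0.6 + 0.3) * 8)
        p2 = hf.make_parameters(2, 0.4, 0.0)
        assert p2.Jsig_phi == pytest.approx(0.05 * 8)
        assert p2.Jsig_phi == pytest.approx(p2.Jsig)  # scale 2 degeneracy
        for p in (p1, p2):
            assert p.J_zeta == p.J and p.Jsig_zeta == p.Jsig
            assert p.vHB_zeta == p.vHB_b
            assert p.Jsig < p.J

    def test_phi_shell_volume_pressure_law(self):
        p = hf.make_parameters(0, 0.3, 0.0)
        assert p.vHB_phi(0.0) == pytest.approx(2.0)
        assert p.vHB_phi(0.25) == pytest.approx(0.0)  # k1 * P = 1
        assert p.vHB_phi(1.0) == 0.0  # clipped, never negative

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            hf.make_parameters(3, 0.3, 0.0)


class TestInitState:
    def test_concentrations(self, params04):
        for n_p, conc in ((2, 0.045), (12, 0.27)):
            st = hf.init_state(params04, 40, n_p, seed=1, start="native")
            c = (40 * 40 - st.n_water) / (40 * 40)
            assert c == pytest.approx(conc)

    def test_cell_counts(self, params04):
        st = hf.init_state(params04, 40, 2, seed=9)
        assert 40 * 40 - st.n_water == 72
        assert st.n_water == 1528

    def test_deterministic(self, params04):
        a = hf.init_state(params04, 20, 3, seed=4, start="native")
        b = hf.init_state(params04, 20, 3, seed=4, start="native")
        assert np.array_equal(a.sigma, b.sigma)
        assert all(
            np.array_equal(x.coords, y.coords) for x, y in zip(a.chains, b.chains)
        )

    def test_no_wall_contact_and_no_overlap(self, params04):
        for start in ("extended", "native"):
            st = hf.init_state(params04, 40, 12, seed=2, start=start)
            assert np.all(st.hydro[:, 0] == 0) and np.all(st.hydro[:, 39] == 0)

    def test_overfull_lattice_rejected(self, params04):
        with pytest.raises(ValueError):
            hf.init_state(params04, 8, 2, seed=0, start="native")


def _three_label_state(params04):
    """A small state with phi, zeta, chi and bulk waters present."""
    chains = [
        ProteinChain(np.array([(2, 3), (3, 3), (3, 4), (2, 4)]), Sequence("LLLL")),
        ProteinChain(np.array([(6, 3), (7, 3), (7, 4), (6, 4)]), Sequence("SSSS")),
        ProteinChain(np.array([(4, 6), (5, 6), (5, 7), (4, 7)]), Sequence("LSSL")),
    ]
    rng = np.random.default_rng(0)
    return hf.LatticeState(
        L=10, v=1.2, chains=chains, sigma=rng.integers(1, 7, (10, 10, 4)).astype(np.int8)
    )


class TestClassification:
    def test_water_labels(self, params04):
        st = _three_label_state(params04)
        assert hf.classify_water(st, (2, 2)) == PHI  # below an L residue
        assert hf.classify_water(st, (6, 2)) == ZETA  # below an S residue
        assert hf.classify_water(st, (0, 0)) == PHI  # wall-adjacent
        assert hf.classify_water(st, (0, 5)) == BULK
        assert hf.classify_water(st, (4, 3)) == PHI  # touches the L block only
        assert hf.classify_water(st, (0, 1)) == BULK  # one row off the wall

    def test_wall_plus_philic_is_mixed(self):
        chains = [ProteinChain(np.array([(1, 1), (2, 1), (2, 2), (1, 2)]), Sequence("SSSS"))]
        rng = np.random.default_rng(1)
        st = hf.LatticeState(
            L=8, v=1.2, chains=chains, sigma=rng.integers(1, 7, (8, 8, 4)).astype(np.int8)
        )
        assert hf.classify_water(st, (1, 0)) == CHI  # wall below, zeta above

    def test_residue_cell_is_domain_error(self, params04):
        st = _three_label_state(params04)
        with pytest.raises(ValueError):
            hf.classify_water(st, (2, 3))

    def test_hb_pair_rules(self, params04):
        st = _three_label_state(params04)
        assert hf.classify_hb_pair(st, (0, 5), (1, 5)) == BULK
        assert hf.classify_hb_pair(st, (2, 2), (3, 2)) == PHI
        assert hf.classify_hb_pair(st, (6, 2), (7, 2)) == ZETA
        # bulk endpoint wins even against a shell endpoint
        assert hf.classify_hb_pair(st, (0, 1), (0, 0)) == BULK

    def test_mixed_adjacency_and_chi_pair(self):
        # the corridor between an L block and an S block: water at (3, y) for
        # y = 3, 4 touches one hydrophobic and one hydrophilic residue -> chi
        chains = [
            ProteinChain(np.array([(1, 3), (2, 3), (2, 4), (1, 4)]), Sequence("LLLL")),
            ProteinChain(np.array([(4, 3), (5, 3), (5, 4), (4, 4)]), Sequence("SSSS")),
        ]
        rng = np.random.default_rng(2)
        st = hf.LatticeState(
            L=10, v=1.2, chains=chains, sigma=rng.integers(1, 7, (10, 10, 4)).astype(np.int8)
        )
        assert hf.classify_water(st, (3, 3)) == CHI
        assert hf.classify_water(st, (3, 4)) == CHI
        assert hf.classify_hb_pair(st, (3, 3), (3, 4)) == CHI
        # a chi water bonded to a bulk water falls back to bulk couplings
        assert hf.classify_water(st, (3, 2)) == BULK
        assert hf.classify_hb_pair(st, (3, 2), (3, 3)) == BULK

    def test_non_neighbor_pair_rejected(self, params04):
        st = _three_label_state(params04)
        with pytest.raises(ValueError):
            hf.classify_hb_pair(st, (0, 0), (2, 0))


class TestPeriodicity:
    def test_shift_in_x_leaves_energies_invariant(self, params04, mj):
        st = _three_label_state(params04)
        shifted = st.copy()
        for c in shifted.chains:
            c.coords[:, 0] += 1
        shifted.sigma = np.roll(st.sigma, 1, axis=0)
        shifted.rebuild_occupancy()
        e0 = hf.total_enthalpy(st, params04, mj)
        e1 = hf.total_enthalpy(shifted, params04, mj)
        assert e1.total == pytest.approx(e0.total, rel=1e-12)
        assert np.array_equal(e0.NHB, e1.NHB)
        assert np.array_equal(e0.Ncoop, e1.Ncoop)


class TestSnapshot:
    def test_round_trip_is_byte_identical(self, params04, tmp_path):
        st = hf.init_state(params04, 12, 2, seed=8, start="native")
        text = hf.save_snapshot(st, tmp_path / "snap.txt", header={"step": 0})
        loaded, meta = hf.load_snapshot(tmp_path / "snap.txt")
        assert meta["step"] == "0"
        assert hf.save_snapshot(loaded, header={"step": 0}) == text
        assert np.array_equal(loaded.sigma, st.sigma)
        assert np.array_equal(loaded.hydro, st.hydro)
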