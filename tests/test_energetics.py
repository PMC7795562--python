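"""Reference Hamiltonian terms against closed forms and brute force."""

import numpy as np
import pytest

import hydrofold as hf
from hydrofold.energetics import density_index, water_pair_histogram
from hydrofold.lattice import BULK, CHI, PHI, ZETA, ProteinChain
from hydrofold.protein import Sequence


def make_state(L, chains, sigma=None, v=1.2, seed=0):
    rng = np.random.default_rng(seed)
    if sigma is None:
        sigma = rng.integers(1, 7, (L, L, 4)).astype(np.int8)
    return hf.LatticeState(L=L, v=v, chains=chains, sigma=sigma)


class TestLJPotential:
    def test_minimum_cutoff_hardcore(self, params04):
        r0 = params04.r0
        assert hf.lj_potential(2 ** (1 / 6) * r0, params04) == pytest.approx(-1.0)
        assert hf.lj_potential(6 * r0, params04) == 0.0
        assert hf.lj_potential(7 * r0, params04) == 0.0
        assert np.isinf(hf.lj_potential(0.9 * r0, params04))
        assert hf.lj_potential(2 * r0, params04) == pytest.approx(-0.0615234375)

    def test_lj_total_against_brute_force(self, params04):
        # near-empty 10x10 box: three waters in a row plus chains elsewhere
        seq = Sequence("L" * 36)
        # fill most of the lattice with residues so only 3 waters remain
        coords = []
        for y in range(10):
            xs = range(10) if y % 2 == 0 else range(9, -1, -1)
            coords.extend((x, y) for x in xs)
        keep = [c for c in coords if c not in ((3, 5), (4, 5), (5, 5))]
        # split into two valid chains around the gap
        chain_cells = []
        cur = []
        for c in coords:
            if c in ((3, 5), (4, 5), (5, 5)):
                if cur:
                    chain_cells.append(cur)
                    cur = []
            else:
                cur.append(c)
        chain_cells.append(cur)
        chains = [
            ProteinChain(np.array(cc), Sequence("L" * len(cc))) for cc in chain_cells
        ]
        st = make_state(10, chains, v=1.2599210498948732)  # r = 2^(1/6) r0
        assert st.n_water == 3
        # brute force: all unordered min-image pairs
        waters = [(x, y) for x in range(10) for y in range(10) if st.hydro[x, y] == 0]
        r = np.sqrt(st.v)
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                dx = abs(waters[i][0] - waters[j][0])
                dx = min(dx, 10 - dx)
                d = np.hypot(dx, waters[i][1] - waters[j][1]) * r
                expected += hf.lj_potential(d, params04)
        assert hf.lj_total(st, params04) == pytest.approx(expected, rel=1e-12)
        # 3 waters in a row at the LJ-minimum spacing: -2 eps + next-neighbour
        assert expected == pytest.approx(
            -2.0 + hf.lj_potential(2 * 2 ** (1 / 6), params04)
        )

    def test_cutoff_volume_kills_lj(self, params04, mj):
        st = make_state(6, [ProteinChain(hf.build_snake_native(16) + 1, Sequence("L" * 16))],
                        v=36.5)
        assert hf.lj_total(st, params04) == 0.0


class TestHBCounts:
    def test_aligned_sigma_gives_full_coop(self, params04):
        st = make_state(6, [], sigma=np.full((6, 6, 4), 3, dtype=np.int8))
        nhb, ncoop = hf.hb_and_coop_counts(st, params04)
        # every molecule: 6 equal pairs; every NN pair bonded
        assert ncoop.sum() == 6 * 36
        assert nhb.sum() == 2 * 36 - 6  # x edges: 36, y edges: 30
        # wall rows are phi, interior bulk
        assert nhb[PHI] > 0 and nhb[BULK] > 0

    def test_single_matched_pair(self, params04):
        sigma = np.zeros((6, 6, 4), dtype=np.int8)
        # make everything mismatched, then one matched +x pair mid-lattice
        sigma[..., 0] = 1
        sigma[..., 1] = 2
        sigma[..., 2] = 3
        sigma[..., 3] = 4
        sigma[2, 3, 0] = 5
        sigma[3, 3, 1] = 5
        st = make_state(6, [], sigma=sigma)
        nhb, _ = hf.hb_and_coop_counts(st, params04)
        assert nhb.sum() == 1
        assert nhb[BULK] == 1

    def test_density_index_gates_all_counts(self, params04):
        st = make_state(6, [], sigma=np.full((6, 6, 4), 2, dtype=np.int8), v=2.5)
        assert density_index(st, params04) == 0
        nhb, ncoop = hf.hb_and_coop_counts(st, params04)
        assert nhb.sum() == 0 and ncoop.sum() == 0

    def test_printed_low_threshold_option(self):
        p = hf.make_parameters(0, 0.4, n_threshold=0.5)
        st = make_state(6, [], sigma=np.full((6, 6, 4), 2, dtype=np.int8), v=1.2)
        assert density_index(st, p) == 0  # liquid at v/v0 = 1.2 forms no HBs


class TestHydrationEnergy:
    def test_scale0_single_phi_bond(self, params04):
        nhb = np.array([0, 1, 0, 0])
        assert hf.hydration_energy(nhb, np.zeros(4, int), params04) == pytest.approx(-9.6)

    def test_scale2_coop(self):
        p = hf.make_parameters(2, 0.4)
        nco = np.array([0, 6, 0, 0])
        assert hf.hydration_energy(np.zeros(4, int), nco, p) == pytest.approx(-2.4)

    def test_zero_shell_counts(self, params04):
        assert hf.hydration_energy(np.zeros(4, int), np.zeros(4, int), params04) == 0.0


class TestProteinEnergies:
    def test_rod_has_no_contact_energy(self, params04, mj):
        st = make_state(40, [ProteinChain(hf.protein.build_rod(36) + 2, hf.default_snake_sequence())])
        assert hf.protein_contact_energy(st, mj) == 0.0

    def test_native_snake_matches_pairwise_sum(self, mj):
        seq = hf.default_snake_sequence()
        conf = hf.build_snake_native(36)
        st = make_state(12, [ProteinChain(conf + 3, seq)])
        expected = sum(
            mj[seq.aa_indices[i], seq.aa_indices[j]]
            for i, j in hf.native_contact_map(conf)
        )
        assert hf.protein_contact_energy(st, mj) == pytest.approx(expected, rel=1e-12)

    def test_two_touching_blocks_add_cross_terms(self, mj, params04):
        sa = Sequence("LLLL")
        sb = Sequence("SSSS")
        a = ProteinChain(np.array([(2, 2), (3, 2), (3, 3), (2, 3)]), sa)
        b = ProteinChain(np.array([(4, 2), (5, 2), (5, 3), (4, 3)]), sb)
        st = make_state(10, [a, b])
        iL, iS = hf.protein.AA_ALPHABET.index("L"), hf.protein.AA_ALPHABET.index("S")
        expected = mj[iL, iL] + mj[iS, iS] + 2 * mj[iL, iS]  # intra ends + 2 cross
        assert hf.protein_contact_energy(st, mj) == pytest.approx(expected, rel=1e-12)

    def test_protein_water_energy_counts_phi_faces(self, params04):
        a = ProteinChain(np.array([(2, 2), (3, 2), (3, 3), (2, 3)]), Sequence("LSSL"))
        st = make_state(10, [a])
        # each residue of a 2x2 block exposes exactly 2 faces; eps_zeta = 0
        assert hf.protein_water_energy(st, params04) == pytest.approx(-2 * 2 * 3.84)

    def test_buried_residues_contribute_nothing(self, params04):
        st = make_state(12, [ProteinChain(hf.build_snake_native(36) + 3,
                                          Sequence("S" * 36))])
        assert hf.protein_water_energy(st, params04) == 0.0  # all-zeta surface


class TestTotals:
    def test_enthalpy_is_sum_of_components(self, params04, mj):
        st = make_state(10, [ProteinChain(hf.build_snake_native(16) + 3,
                                          Sequence("LSLS" * 4))], seed=3)
        e = hf.total_enthalpy(st, params04, mj)
        parts = (
            e.U_lj + e.E_hb_bulk + e.E_coop_bulk + e.E_hb_shell
            + e.E_coop_shell + e.E_mj + e.E_pw
        )
        assert e.total == pytest.approx(parts)
        assert e.E_hb_bulk == pytest.approx(-params04.J * e.NHB[BULK])
        assert (e.NHB >= 0).all() and (e.Ncoop >= 0).all()
        assert e.NHB.sum() <= 2 * 10 * 10

    def test_volume_no_bonds_is_base(self, params04):
        st = make_state(6, [], sigma=np.full((6, 6, 4), 2, dtype=np.int8), v=2.5)
        vb = hf.total_volume(st, params04)
        assert vb.total == pytest.approx(36 * 2.5)

    def test_phi_bond_volume_at_ambient_pressure(self, params04):
        # all-aligned sigma on a water-only box: every wall-row pair is phi
        st = make_state(6, [], sigma=np.full((6, 6, 4), 1, dtype=np.int8))
        nhb, _ = hf.hb_and_coop_counts(st, params04)
        vb = hf.total_volume(st, params04)
        expected = (
            36 * 1.2
            + (nhb[BULK] + nhb[ZETA]) * 0.5
            + nhb[CHI] * params04.vHB_chi()
            + nhb[PHI] * 2.0
        )
        assert vb.total == pytest.approx(expected)

    def test_pressure_collapses_phi_volume(self):
        p = hf.make_parameters(0, 0.4, P_star=0.25)  # k1 * P = 1
        st = make_state(6, [], sigma=np.full((6, 6, 4), 1, dtype=np.int8))
        vb = hf.total_volume(st, p)
        nhb, _ = hf.hb_and_coop_counts(st, p)
        assert nhb[PHI] > 0
        assert vb.V_phi == 0.0


class TestPairHistogram:
    def test_total_pair_count(self, params04):
        st = make_state(8, [])
        hist = water_pair_histogram(st)
        # 64 waters: all pairs within sqrt(36) of min-image distance
        n = 0
        for i in range(64):
            for j in range(i + 1, 64):
                x1, y1 = divmod(i, 8)
                x2, y2 = divmod(j, 8)
                dx = min(abs(x1 - x2), 8 - abs(x1 - x2))
                if dx * dx + (y1 - y2) ** 2 <= 36:
                    n += 1
        assert hist.sum() == n
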