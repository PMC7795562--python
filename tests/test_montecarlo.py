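"""Monte Carlo moves: detailed balance, bit-identity, composition, drift."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import hydrofold as hf
from hydrofold.lattice import ProteinChain
from hydrofold.montecarlo import Simulation, detect_equilibration
from hydrofold.protein import Sequence, is_valid_conformation

from conftest import block_se, state_digest


def zero_coupling_params():
    base = hf.make_parameters(0, 0.4, 0.0)
    return dataclasses.replace(
        base, J=0.0, Jsig=0.0, J_phi=0.0, Jsig_phi=0.0, eps_phi=0.0, eps_zeta=0.0
    )


class TestRejectionAndValidity:
    def test_rejected_moves_leave_state_bit_identical(self, small_sim):
        sim = small_sim
        sim.step(5)
        rng = np.random.default_rng(0)
        n_rejected = 0
        for _ in range(300):
            before = state_digest(sim)
            kind = ("shift", "rotation", "crankshaft", "pivot")[rng.integers(4)]
            out = sim.attempt_global_move(kind, int(rng.integers(2)))
            if not out.accepted:
                n_rejected += 1
                assert state_digest(sim) == before
        assert n_rejected > 50  # dense state: plenty of rejections exercised

    def test_chains_stay_valid_after_many_steps(self, small_sim):
        sim = small_sim
        sim.step(150)
        st = sim.state
        for c in st.chains:
            assert is_valid_conformation(c.coords)
            assert np.all((c.coords[:, 1] >= 0) & (c.coords[:, 1] < st.L))
        st.rebuild_occupancy()  # raises on overlap or broken connectivity

    def test_volume_below_hard_core_rejected(self, small_sim):
        before = state_digest(small_sim)
        out = small_sim.attempt_volume_move(dv=-10.0)
        assert not out.accepted
        assert state_digest(small_sim) == before

    def test_corner_flip_on_straight_segment_rejected(self, params04):
        chain = ProteinChain(hf.protein.build_rod(8) + np.array([2, 5]), Sequence("S" * 8))
        rng = np.random.default_rng(1)
        st = hf.LatticeState(L=12, v=1.2, chains=[chain],
                             sigma=rng.integers(1, 7, (12, 12, 4)).astype(np.int8))
        sim = Simulation(st, params04, seed=2)
        for x in range(3, 9):
            out = sim.attempt_corner_flip((x, 5))
            assert not out.accepted

    def test_corner_flip_at_bend_moves_residue(self, params04):
        coords = np.array([(2, 2), (3, 2), (3, 3), (3, 4), (2, 4)])
        chain = ProteinChain(coords, Sequence("SSSSS"))
        rng = np.random.default_rng(1)
        st = hf.LatticeState(L=12, v=1.2, chains=[chain],
                             sigma=rng.integers(1, 7, (12, 12, 4)).astype(np.int8))
        sim = Simulation(st, params04, seed=2)
        # residue 1 at (3,2) sits at a bend; the diagonal (2,3) is water
        for trial in range(200):
            out = sim.attempt_corner_flip((3, 2))
            if out.accepted:
                break
        assert out.accepted
        assert tuple(sim.state.chains[0].coords[1]) == (2, 3)
        assert sim.verify_bookkeeping() < 1e-9


class TestMetropolisStatistics:
    def test_volume_move_acceptance_matches_boltzmann(self, params04, mj):
        # repeat an identical uphill proposal from an identical state
        state = hf.init_state(params04, 10, 1, seed=3, start="native", n_residues=16,
                              sequence=Sequence("LSLS" * 4))
        sim = Simulation(state, params04, matrix=mj, seed=5)
        dv = 0.04
        h0 = sim.total_enthalpy()
        v0 = sim.total_volume()
        st2 = sim.state.copy()
        st2.v += dv
        ref = hf.total_enthalpy(st2, params04, mj)
        dH = ref.total - h0
        assert dH > 0  # uphill on the LJ branch chosen here
        p_expect = np.exp(-dH / params04.T_star)
        acc = 0
        n = 400
        for k in range(n):
            sim.reseed(1000 + k)
            out = sim.attempt_volume_move(dv=dv)
            if out.accepted:
                acc += 1
                sim.fstate[0] -= dv  # restore volume for the next trial
                from hydrofold import _kernels as K
                K.build_u_tab(sim.u_tab, sim.fstate[0])
                sim.istate[3] = 1
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(acc / n - p_expect) < 4 * se + 1e-3

    def test_zero_coupling_sigma_flips_always_accept_and_uniformize(self):
        p = zero_coupling_params()
        st = hf.init_state(p, 10, 0, seed=7)
        sim = Simulation(st, p, seed=11)
        # decorrelated snapshots: ~200 flips/step on 400 variables
        counts = np.zeros(7, dtype=np.int64)
        matches = []
        L = 10
        for _ in range(40):
            sim.step(20)
            sigma = sim._state.sigma
            counts += np.bincount(sigma.ravel(), minlength=7)
            for x in range(L):
                for y in range(L):
                    matches.append(sigma[x, y, 0] == sigma[(x + 1) % L, y, 1])
        assert sim.acceptance_rates()["sigma"] == 1.0
        total = counts.sum()
        se_bin = np.sqrt(total * (1 / 6) * (5 / 6)) / total
        assert np.all(np.abs(counts[1:] / total - 1 / 6) < 4 * se_bin)
        # facing-pair agreement probability 1/q
        frac = np.mean(matches)
        assert abs(frac - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / len(matches))

    def test_pair_hb_probability_closed_form(self):
        """Isolated pair, no cooperativity: P(HB) = e^(J/T) / (e^(J/T) + q - 1)."""
        base = hf.make_parameters(0, 0.4, 0.0)
        p = dataclasses.replace(base, Jsig=0.0, Jsig_phi=0.0)
        fx = hf.generate_fixture("two-waters", seed=3)
        sim = Simulation(fx.state.copy(), p, seed=21,
                         volume_moves=False, protein_moves=False)
        sim.step(500)
        # HB dwell times here are ~10^3 steps, so use a long series and
        # few large blocks for the error estimate
        vals = []
        for _ in range(24000):
            sim.step(1)
            vals.append(sim.nhb_counts().sum())
        vals = np.asarray(vals, dtype=float)
        beta_j = p.J / p.T_star  # zeta couplings equal bulk ones
        expect = np.exp(beta_j) / (np.exp(beta_j) + p.q - 1)
        assert abs(vals.mean() - expect) < 3 * block_se(vals, nblocks=12) + 1e-3


class TestStepComposition:
    def test_local_attempt_budget(self, params04):
        st = hf.init_state(params04, 10, 0, seed=1)
        sim = Simulation(st, params04, seed=3)
        n = 300
        sim.step(n)
        local = sim.acc[4, 0] + sim.acc[5, 0]  # corner + sigma attempts
        expect = n * (1 + 4 * 100) / 2
        assert abs(local / expect - 1) < 0.1
        assert sim.acc[6, 0] == n  # one volume attempt per step
        assert sim.acc[:4, 0].sum() == 0  # no proteins -> no global attempts

    def test_global_attempts_scale_with_np(self, small_sim):
        n = 50
        small_sim.step(n)
        assert small_sim.acc[:4, 0].sum() == n * 2  # Np attempts per step

    def test_same_seed_reproduces_records(self, params04, mj):
        def fresh():
            st = hf.init_state(params04, 10, 1, seed=2, start="native",
                               n_residues=16, sequence=Sequence("LSSL" * 4))
            return Simulation(st, params04, matrix=mj, seed=9)

        a = fresh().run(40, record_stride=2)
        b = fresh().run(40, record_stride=2)
        pd.testing.assert_frame_equal(a, b)

    def test_recording_stride_does_not_alter_trajectory(self, params04, mj):
        def final_digest(stride):
            st = hf.init_state(params04, 10, 1, seed=2, start="native",
                               n_residues=16, sequence=Sequence("LSSL" * 4))
            sim = Simulation(st, params04, matrix=mj, seed=9)
            sim.run(40, record_stride=stride)
            return state_digest(sim)

        assert final_digest(1) == final_digest(40)


class TestBookkeepingAgainstReference:
    @pytest.mark.parametrize("L,n_res", [(10, 16), (14, 16)])
    def test_incremental_matches_recompute_both_lj_paths(self, params04, mj, L, n_res):
        # L <= 13 exercises the all-pairs minimum-image branch, L > 13 offsets
        st = hf.init_state(params04, L, 1, seed=6, start="native",
                           n_residues=n_res, sequence=Sequence("LSSL" * (n_res // 4)))
        sim = Simulation(st, params04, matrix=mj, seed=13)
        sim.step(60)
        assert sim.verify_bookkeeping() < 1e-9


class TestEquilibrationDetection:
    @staticmethod
    def frame(values):
        n = len(values)
        return pd.DataFrame(
            {"step": np.arange(n), "Nc": values, "Ic": values, "Mc": values}
        )

    def test_white_noise_equilibrated_at_window_start(self):
        rng = np.random.default_rng(0)
        df = self.frame(rng.normal(0.5, 0.05, 400))
        assert detect_equilibration(df, window=100) == 0

    def test_pure_ramp_never_equilibrates(self):
        df = self.frame(np.linspace(0, 1, 300))
        assert detect_equilibration(df, window=100) is None

    def test_ramp_then_plateau_detected_near_ramp_end(self):
        rng = np.random.default_rng(1)
        ramp = np.linspace(0, 1, 150)
        plateau = 1 + rng.normal(0, 0.02, 250)
        df = self.frame(np.concatenate([ramp, plateau]))
        found = detect_equilibration(df, window=100)
        assert found is not None
        assert 100 <= found <= 200  # within window resolution of the ramp end

    def test_window_longer_than_series_is_an_error(self):
        df = self.frame(np.zeros(10))
        with pytest.raises(ValueError):
            detect_equilibration(df, window=11)

    def test_constant_series_passes(self):
        df = self.frame(np.full(50, 0.25))
        assert detect_equilibration(df, window=20) == 0

    def test_run_config_validation(self):
        from hydrofold.montecarlo import RunConfig

        assert RunConfig(n_steps=10, record_stride=2).record_stride == 2
        with pytest.raises(ValueError):
            RunConfig(n_steps=0)
        with pytest.raises(ValueError):
            RunConfig(n_steps=5, record_stride=0)
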