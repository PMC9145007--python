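"""Stationary CME solver: enumeration, generators, channels, and limits."""

import numpy as np
import pytest

from retrochannel import cme
from retrochannel.cme import (
    NonErgodicError,
    a_hat,
    build_generator,
    channel_from_cme,
    enumerate_states,
    mi_from_cme,
    solve_model,
    stationary_distribution,
)
from retrochannel.networks import RateParameters, build_model


@pytest.fixture
def siso(unit_rates):
    return build_model("ISOLATED_SISO", unit_rates)


def state_dicts(model, states):
    return [dict(zip(model.species, s)) for s in states]


class TestEnumeration:
    def test_siso_symbol_one_has_three_states(self, siso):
        states = state_dicts(siso, enumerate_states(siso, 1))
        expected = [
            {"I1": 1, "E": 1, "M1": 0, "Z1": 0},
            {"I1": 0, "E": 0, "M1": 1, "Z1": 0},
            {"I1": 0, "E": 1, "M1": 0, "Z1": 1},
        ]
        assert len(states) == 3
        for e in expected:
            assert e in states

    def test_siso_symbol_zero_is_a_single_empty_class(self, siso):
        states = state_dicts(siso, enumerate_states(siso, 0))
        assert states == [{"I1": 0, "E": 1, "M1": 0, "Z1": 0}]

    def test_mimo_enzyme_competition_excludes_double_complex(self, unit_rates):
        m = build_model("ISOLATED_MIMO", unit_rates)
        states = enumerate_states(m, (1, 1))
        assert len(states) == 8  # {I,M,Z} x {I,M,Z} minus (M1, M2)
        i_m1 = m.species.index("M1")
        i_m2 = m.species.index("M2")
        assert all(s[i_m1] + s[i_m2] <= 1 for s in states)

    def test_ordering_is_canonical(self, siso):
        states = enumerate_states(siso, 1)
        assert states == sorted(states)

    def test_enumeration_cap_guards_large_totals(self, siso):
        with pytest.raises(MemoryError):
            enumerate_states(siso, 200, max_states=10)


class TestGenerator:
    def test_siso_chain_rates(self, siso):
        states = enumerate_states(siso, 1)
        Q = build_generator(siso, states)
        d = state_dicts(siso, states)
        i_free = d.index({"I1": 1, "E": 1, "M1": 0, "Z1": 0})
        i_cplx = d.index({"I1": 0, "E": 0, "M1": 1, "Z1": 0})
        i_out = d.index({"I1": 0, "E": 1, "M1": 0, "Z1": 1})
        assert Q[i_free, i_cplx] == pytest.approx(1.0)  # k0+ * I * E
        assert Q[i_cplx, i_free] == pytest.approx(1.0)  # k0-
        assert Q[i_cplx, i_out] == pytest.approx(1.0)  # c1
        assert Q[i_out, i_free] == pytest.approx(1.0)  # c2
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_empty_class_generator_is_zero(self, siso):
        states = enumerate_states(siso, 0)
        Q = build_generator(siso, states)
        assert Q.shape == (1, 1) and Q[0, 0] == 0.0

    def test_rows_sum_to_zero_for_all_topologies(self, unit_rates):
        rates = RateParameters.uniform(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, n_sites=2)
        m = build_model("MIMO_N_DOWNSTREAM", rates, n_downstream=2)
        states = enumerate_states(m, (1, 1))
        Q = build_generator(m, states)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert (Q - np.diag(np.diag(Q)) >= 0).all()


class TestStationary:
    def test_hand_solved_three_state_chain(self, siso, fixtures):
        dist = solve_model(siso, 1)
        expected = dict(
            zip(
                [
                    (1, 0, 0, 1),  # (I1, M1, Z1, E) free
                    (0, 1, 0, 0),  # complex
                    (0, 0, 1, 1),  # output
                ],
                fixtures["siso_unit_rates"].expected["pi"],
            )
        )
        for s, p in zip(dist.states, dist.probs):
            assert p == pytest.approx(expected[s], abs=1e-12)

    def test_single_state_class(self, siso):
        dist = solve_model(siso, 0)
        assert dist.probs.tolist() == [1.0]

    def test_stationary_matches_nullspace_oracle(self):
        """Dense solve vs an independent eigen-decomposition null space."""
        rng = np.random.default_rng(3)
        Q = rng.uniform(0.1, 2.0, size=(5, 5))
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(5)] = -Q.sum(axis=1)
        pi = stationary_distribution(Q, start=0)
        w, v = np.linalg.eig(Q.T)
        k = np.argmin(np.abs(w))
        oracle = np.real(v[:, k])
        oracle = oracle / oracle.sum()
        assert np.abs(pi - oracle).max() < 1e-10
        assert np.abs(pi @ Q).max() < 1e-10

    def test_multiple_closed_classes_reported(self):
        # two disconnected 1-state absorbing classes reachable from a fork
        Q = np.array([[-2.0, 1.0, 1.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(NonErgodicError):
            stationary_distribution(Q, start=0)

    def test_residual_contract_on_all_topologies(self, unit_rates):
        rates = RateParameters.uniform(1.3, 0.7, 0.9, 1.1, 2.0, 0.5, n_sites=2)
        for topo, n, q in [
            ("ISOLATED_SISO", 0, None),
            ("SISO_N_DOWNSTREAM", 2, None),
            ("ISOLATED_MIMO", 0, None),
            ("MIMO_N_DOWNSTREAM", 2, None),
            ("TWO_SISO_MAC", 2, 1),
        ]:
            m = build_model(topo, rates, n_downstream=n, q_connected=q)
            states = enumerate_states(m, (1, 1))
            Q = build_generator(m, states)
            dist = solve_model(m, 1, 1)
            assert np.abs(dist.probs @ Q).max() < 1e-10
            assert dist.probs.min() >= 0.0


class TestChannel:
    def test_siso_unit_rates_a_hat(self, siso, fixtures):
        assert a_hat(siso) == pytest.approx(
            fixtures["siso_unit_rates"].expected["a_hat"], abs=1e-12
        )

    def test_zero_symbol_never_produces_output(self, unit_rates):
        rates = RateParameters.uniform(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, n_sites=1)
        for topo, n in [("ISOLATED_SISO", 0), ("SISO_N_DOWNSTREAM", 1)]:
            m = build_model(topo, rates, n_downstream=n)
            assert cme.prob_z1_zero(m, 0) == pytest.approx(1.0, abs=1e-14)

    def test_joint_has_z_channel_structure(self, siso):
        ch = channel_from_cme(siso, p01=0.4)
        joint = ch.joint
        assert joint[0, 1] == 0.0
        assert joint.sum() == pytest.approx(1.0)
        assert joint[0].sum() == pytest.approx(0.4)
        assert joint[1].sum() == pytest.approx(0.6)

    def test_noncyclic_circuit_absorbs_in_output(self, unit_rates):
        rates = RateParameters(1.0, 1.0, 1.0, 0.0)
        m = build_model("ISOLATED_SISO", rates)
        assert a_hat(m) == pytest.approx(0.0, abs=1e-14)

    def test_huge_recycling_kills_information(self):
        rates = RateParameters(1.0, 1.0, 1.0, 1e6)
        m = build_model("ISOLATED_SISO", rates)
        assert mi_from_cme(m) < 1e-5

    def test_mi_equals_channel_entropy_computation(self, siso):
        from retrochannel.info import mi_z_channel

        assert mi_from_cme(siso) == pytest.approx(mi_z_channel(a_hat(siso), 0.5))

    def test_mi_example_from_hand_solved_joint(self, siso):
        # A = 3/4, P01 = 1/2 -> joint [[1/2, 0], [3/8, 1/8]]
        from retrochannel.info import mutual_information

        expected = mutual_information([[0.5, 0.0], [0.375, 0.125]])
        assert mi_from_cme(siso) == pytest.approx(expected, abs=1e-14)

    def test_degenerate_prior_gives_zero_mi(self, siso):
        assert mi_from_cme(siso, (1.0, 0.0, 0.5, 0.5)) == pytest.approx(0.0, abs=1e-14)

    def test_mimo_a_hat_is_prior_mixture_of_branch_conditionals(self, unit_rates):
        m = build_model("ISOLATED_MIMO", unit_rates)
        a_i2_0 = cme.prob_z1_zero(m, 1, 0)
        a_i2_1 = cme.prob_z1_zero(m, 1, 1)
        assert a_hat(m, (0.3, 0.7)) == pytest.approx(0.3 * a_i2_0 + 0.7 * a_i2_1)
        # the i2 = 0 branch is exactly the isolated SISO conditional
        siso = build_model("ISOLATED_SISO", unit_rates)
        assert a_i2_0 == pytest.approx(a_hat(siso), abs=1e-12)


class TestLoadMonotonicity:
    def test_a_hat_nondecreasing_and_mi_nonincreasing_in_n(self):
        from retrochannel.info import mi_z_channel

        prev_a, prev_mi = -1.0, np.inf
        for n in range(0, 5):
            rates = RateParameters.uniform(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, n_sites=n)
            topo = "SISO_N_DOWNSTREAM" if n else "ISOLATED_SISO"
            m = build_model(topo, rates, n_downstream=n)
            a = a_hat(m)
            mi = mi_z_channel(a, 0.5)
            assert a >= prev_a - 1e-12
            assert mi <= prev_mi + 1e-12
            prev_a, prev_mi = a, mi

    @pytest.mark.parametrize("q,reference", [(0, "ISOLATED_SISO"), (3, "SISO_N_DOWNSTREAM")])
    def test_mac_interpolates_between_isolated_and_loaded(self, q, reference):
        n = 3
        rates = RateParameters.uniform(1.0, 2.0, 0.7, 1.3, 1.0, 0.8, n_sites=n)
        mac = build_model("TWO_SISO_MAC", rates, n_downstream=n, q_connected=q)
        ref_n = 0 if reference == "ISOLATED_SISO" else n
        ref_rates = RateParameters.uniform(1.0, 2.0, 0.7, 1.3, 1.0, 0.8, n_sites=ref_n)
        ref = build_model(reference, ref_rates, n_downstream=ref_n)
        assert a_hat(mac) == pytest.approx(a_hat(ref), abs=1e-10)
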