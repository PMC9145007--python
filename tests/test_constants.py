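"""Closed-form retroactivity constants: values, limits, orderings, CME agreement."""

import warnings

import numpy as np
import pytest

from retrochannel import cme
from retrochannel.constants import (
    RegimeWarning,
    a0,
    a0_limit_c2_to_inf,
    a0_mimo,
    aN,
    aN_limit_c2_to_inf,
    aN_limit_n_to_inf,
    aN_mimo,
    aN_noncyclic,
    aQ_mac,
    b_const,
    b_const_numeric,
    g_const_numeric,
)
from retrochannel.info import mi_z_channel
from retrochannel.networks import build_model
from retrochannel.synthetic import ladder_rates, sample_rates


class TestIsolatedConstant:
    def test_substitution_example(self):
        assert a0(1.0, 1.0, 1.0).value == pytest.approx(2 / 3)

    def test_noncyclic_limit_is_zero(self):
        assert a0(5.0, 2.0, 0.0).value == 0.0

    def test_large_recycling_limit_is_one(self):
        assert a0(1.0, 1.0, 1e9).value == pytest.approx(1.0, abs=1e-8)
        assert a0_limit_c2_to_inf(1.0, 1.0) == 1.0

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            a0(1.0, 0.0, 0.0)


class TestLoadedConstant:
    def test_no_downstream_reduces_to_a0(self):
        assert aN(1.3, 0.7, 0.4, ()).value == pytest.approx(a0(1.3, 0.7, 0.4).value)

    def test_substitution_example(self):
        assert aN(1.0, 1.0, 1.0, (1.0,)).value == pytest.approx(3 / 4)

    def test_infinite_load_limit(self):
        big = aN(1.0, 1.0, 1.0, (1.0,) * 10**6)
        assert abs(big.value - 1.0) < 1e-5
        assert aN_limit_n_to_inf(1.0, 1.0, 1.0, 1.0) == 1.0

    def test_large_recycling_limit(self):
        assert aN(1.0, 1.0, 1e9, (1.0,) * 3).value == pytest.approx(1.0, abs=1e-8)
        assert aN_limit_c2_to_inf(1.0, 1.0, (1.0,) * 3) == 1.0

    def test_nondecreasing_in_site_affinity(self):
        vals = [aN(1.0, 1.0, 1.0, (k3,)).value for k3 in (10.0, 1.0, 0.1)]
        assert vals[0] < vals[1] < vals[2]  # stronger binding (smaller k3), more load

    def test_zero_k3_reported(self):
        with pytest.raises(ValueError):
            aN(1.0, 1.0, 1.0, (0.0,))


class TestNoncyclicConstant:
    def test_no_downstream(self):
        assert aN_noncyclic(1.0, ()).value == 0.0

    def test_single_unit_site(self):
        assert aN_noncyclic(1.0, (1.0,)).value == pytest.approx(0.5)

    def test_weak_binding_unloads(self):
        assert aN_noncyclic(1.0, (1e9,)).value == pytest.approx(0.0, abs=1e-8)

    def test_matches_aN_at_c2_zero(self):
        assert aN_noncyclic(0.7, (2.0, 0.5)).value == pytest.approx(
            aN(1.0, 0.7, 0.0, (2.0, 0.5)).value
        )


class TestCrossBranchConstant:
    def test_substitution_example(self):
        b = b_const(1.0, 1.0, 0.01)  # exactly at the regime threshold
        assert b.value == pytest.approx((8 + 9 * 0.01) / (11 + 11 * 0.01))

    def test_out_of_regime_warns(self):
        with pytest.warns(RegimeWarning):
            b_const(1.0, 1.0, 0.5)

    def test_zero_catalysis_limit(self):
        kp, km = 2.0, 3.0
        expected = (3 * kp**2 + km**2 + 4 * km * kp) / (5 * kp**2 + km**2 + 5 * km * kp)
        assert b_const(kp, km, 0.0).value == pytest.approx(expected)

    def test_in_regime_no_warning(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            b_const(100.0, 100.0, 1.0)

    def test_cme_value_converges_to_closed_form(self):
        errs = []
        for scale in (10.0, 100.0, 1000.0):
            r = ladder_rates(scale)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RegimeWarning)
                b = b_const(r.k0_plus, r.k0_minus, r.c1).value
            errs.append(abs(b_const_numeric(r).value - b))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3


class TestMixtures:
    def test_a0_mimo_endpoints(self):
        assert a0_mimo(0.6, 0.8, 1.0, 0.0).value == pytest.approx(0.6)
        assert a0_mimo(0.6, 0.8, 0.0, 1.0).value == pytest.approx(0.8)

    def test_a0_mimo_never_below_a0(self):
        r = ladder_rates(100.0)
        a = a0(r.k0, r.c1, r.c2).value
        b = b_const(r.k0_plus, r.k0_minus, r.c1).value
        for p12 in np.linspace(0.0, 1.0, 21):
            assert a0_mimo(a, b, 1.0 - p12, p12).value >= a - 1e-12

    def test_aN_mimo_endpoints(self):
        assert aN_mimo(0.7, 0.9, 1.0, 0.0).value == pytest.approx(0.7)
        assert aN_mimo(0.7, 0.9, 0.0, 1.0).value == pytest.approx(0.9)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            a0_mimo(0.5, 0.5, 0.7, 0.7)


class TestMacConstant:
    def test_endpoints(self):
        k3 = (1.0, 2.0, 0.5)
        assert aQ_mac(1.0, 1.0, 1.0, k3, 0).value == pytest.approx(
            a0(1.0, 1.0, 1.0).value
        )
        assert aQ_mac(1.0, 1.0, 1.0, k3, 3).value == pytest.approx(
            aN(1.0, 1.0, 1.0, k3).value
        )

    def test_substitution_example(self):
        assert aQ_mac(1.0, 1.0, 1.0, (1.0, 1.0), 1).value == pytest.approx(3 / 4)

    def test_nondecreasing_in_q(self):
        k3 = (1.0,) * 4
        vals = [aQ_mac(1.0, 1.0, 1.0, k3, q).value for q in range(5)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            aQ_mac(1.0, 1.0, 1.0, (1.0,), 2)


class TestNumericG:
    def test_collapses_to_b_without_downstream(self):
        r = ladder_rates(100.0, n_sites=1)
        g0 = g_const_numeric(r, n_downstream=0)
        assert g0.value == pytest.approx(b_const_numeric(r).value, abs=1e-12)

    def test_exceeds_b_in_fast_binding_regime(self):
        r = ladder_rates(100.0, n_sites=1)
        assert g_const_numeric(r).value > b_const_numeric(r).value


class TestFastBindingAgreement:
    """|A_hat(CME) - closed form| shrinks along the binding-speed ladder."""

    @pytest.mark.parametrize(
        "topology,n",
        [("ISOLATED_SISO", 0), ("SISO_N_DOWNSTREAM", 2)],
    )
    def test_ladder_convergence(self, topology, n):
        errs = []
        for scale in (10.0, 100.0, 1000.0):
            r = ladder_rates(scale, n_sites=n)
            m = build_model(topology, r, n_downstream=n)
            closed = (
                aN(r.k0, r.c1, r.c2, r.k3).value if n else a0(r.k0, r.c1, r.c2).value
            )
            errs.append(abs(cme.a_hat(m) - closed))
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 1e-2 and errs[2] < 1e-3


@pytest.fixture(scope="module")
def draws():
    return sample_rates("fast_binding", 30, seed=11, n_sites=1, equal_catalytic=True)


class TestOrderingBattery:
    """Random fast-binding draws reproduce the A-constant orderings."""

    def test_orderings_and_mi_antimonotonicity(self, draws):
        for d in draws:
            r = d.rates
            a_iso = a0(r.k0, r.c1, r.c2).value
            a_load = aN(r.k0, r.c1, r.c2, r.k3).value
            b = b_const(r.k0_plus, r.k0_minus, r.c1, r.omega).value
            g = g_const_numeric(r).value
            a0m = a0_mimo(a_iso, b, 0.5, 0.5).value
            aNm = aN_mimo(a_load, g, 0.5, 0.5).value
            assert a_iso <= a0m + 1e-12
            assert a_load <= aNm + 1e-12
            assert a_iso <= a_load + 1e-12
            assert b <= g + 1e-12
            for lo, hi in [(a_iso, a0m), (a_iso, a_load), (a_load, aNm)]:
                if hi > lo + 1e-12:
                    assert mi_z_channel(hi, 0.5) < mi_z_channel(lo, 0.5)

    def test_mac_interpolation_within_draws(self, draws):
        for d in draws[:10]:
            r = d.rates
            k3 = r.k3 * 3
            vals = [aQ_mac(r.k0, r.c1, r.c2, k3, q).value for q in range(4)]
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
            assert vals[0] == pytest.approx(a0(r.k0, r.c1, r.c2).value)
            assert vals[-1] == pytest.approx(aN(r.k0, r.c1, r.c2, k3).value)
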