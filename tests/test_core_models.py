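"""Closed-form rebinding theory: printed values, limits and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rebindkin import core_models as cm

log_rate = st.floats(min_value=-4, max_value=8)


class TestDamkohler:
    @pytest.mark.parametrize(
        "ka_p, rmax, r, kt, expected",
        [
            (5e7, 20.0, 0.0, 1e7, 100.0),   # strongly transport-limited surface
            (5e7, 20.0, 0.0, 1e8, 10.0),
            (5e7, 20.0, 0.0, 1e9, 1.0),
            (5e7, 20.0, 20.0, 1e7, 0.0),    # saturated surface: no free probe
            (1e7, 3000.0, 0.0, 1e9, 30.0),
        ],
    )
    def test_values(self, ka_p, rmax, r, kt, expected):
        assert cm.damkohler_number(ka_p, rmax, r, kt) == pytest.approx(expected)

    def test_monotone_decreasing_in_response(self):
        r = np.linspace(0, 20, 50)
        da = cm.damkohler_number(5e7, 20.0, r, 1e7)
        assert np.all(np.diff(da) < 0)

    def test_rejects_nonpositive_kt_and_bad_response(self):
        with pytest.raises(cm.InvalidParameterError):
            cm.damkohler_number(5e7, 20.0, 0.0, 0.0)
        with pytest.raises(cm.InvalidParameterError):
            cm.damkohler_number(5e7, 20.0, 21.0, 1e7)


class TestHydrogelResistance:
    def test_tanh_values(self):
        # gamma chosen via Dgel*Kpart/(ka'P) = Hgel^2 -> gamma = 1
        tg, gamma = cm.hydrogel_resistance_factor(1e-7, 1e-11, 1.0, 1e6, 1e-3)
        assert gamma == pytest.approx(1.0)
        assert tg == pytest.approx(0.7615941559557649)

    def test_limits(self):
        # zero reaction flux -> no resistance
        assert cm.hydrogel_resistance_factor(1e-7, 1e-11, 0.5, 0.0, 1e-3) == (1.0, 0.0)
        # strong flux: T_gamma ~ 1/gamma
        tg, gamma = cm.hydrogel_resistance_factor(1e-6, 1e-12, 0.1, 1e9, 1e-2)
        assert tg == pytest.approx(1.0 / gamma, rel=1e-6)

    @given(st.floats(1e-9, 1e-5), st.floats(1e-13, 1e-9), st.floats(0.01, 1.0),
           st.floats(1e2, 1e9), st.floats(1e-6, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, hgel, dgel, kpart, ka_p, p):
        tg, gamma = cm.hydrogel_resistance_factor(hgel, dgel, kpart, ka_p, p)
        assert 0 < tg <= 1
        assert gamma >= 0


class TestMassTransportCoefficient:
    def test_printed_arithmetic(self):
        spec = cm.TransportSpec(nu_c=0.1, D=5e-10, h=20e-6, l=0.5e-3)
        assert cm.mass_transport_coefficient(spec) == pytest.approx(
            0.1738584483429038, rel=1e-12)

    @pytest.mark.parametrize("variant", ["printed", "leveque"])
    def test_cube_root_flow_scaling_and_linearity(self, variant):
        s1 = cm.TransportSpec(nu_c=0.1)
        s2 = cm.TransportSpec(nu_c=0.2)
        k1 = cm.mass_transport_coefficient(s1, variant=variant)
        k2 = cm.mass_transport_coefficient(s2, variant=variant)
        assert k2 / k1 == pytest.approx(2 ** (1 / 3), rel=1e-12)
        assert cm.mass_transport_coefficient(s1, t_gamma=0.5, variant=variant) \
            == pytest.approx(0.5 * k1, rel=1e-12)

    def test_unknown_variant(self):
        with pytest.raises(cm.InvalidParameterError):
            cm.mass_transport_coefficient(cm.TransportSpec(), variant="bogus")


class TestPartitionFunctions:
    def test_half_inhibition_at_kd_equals_kt(self):
        assert cm.partition_function_f(10.0, 10.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("kd, kt, expected", [(0.0, 5.0, 1.0), (30.0, 10.0, 0.25)])
    def test_values(self, kd, kt, expected):
        assert cm.partition_function_f(kd, kt) == pytest.approx(expected)

    @given(log_rate, log_rate)
    @settings(max_examples=50, deadline=None)
    def test_f_monotone_decreasing_in_kd_over_kt(self, lk1, lk2):
        kt = 10.0
        kd1, kd2 = sorted((10.0**lk1, 10.0**lk2))
        assert cm.partition_function_f(kd1, kt) >= cm.partition_function_f(kd2, kt)

    @pytest.mark.parametrize("kinact, kt, expected",
                             [(0.0, 3.0, 1.0), (3.0, 3.0, 2.0), (1.0, 10.0, 1.1)])
    def test_alkylation_partition(self, kinact, kt, expected):
        assert cm.alkylation_partition_z(kinact, kt) == pytest.approx(expected)


class TestRebindingFactor:
    def test_no_probe_means_no_rebinding(self):
        k = cm.KineticConstants(ka=1e6, kd=0.1, ka_p=1e6, kd_p=0.05)
        assert cm.rebinding_factor_alpha(k, 100.0, 0.0, 1e-6).alpha == 1.0

    def test_blank_equal_partition(self):
        k = cm.KineticConstants(ka_p=1e6, kd_p=0.05)
        res = cm.rebinding_factor_alpha(k, 1e6 * 1e-3, 1e-3, 0.0)
        assert res.alpha == pytest.approx(0.5)

    def test_workflow_constants_arithmetic(self):
        # oracle: direct evaluation of beta/(beta + ka'P) with fit-derived
        # constants of the probe/target pair
        k = cm.KineticConstants(ka=3.07e6, kd=0.125, ka_p=8.5e4, kd_p=0.075)
        res = cm.rebinding_factor_alpha(k, 10.55, 4.66e-4, 4e-6)
        assert res.f == pytest.approx(0.9882903981264638, rel=1e-12)
        assert res.beta == pytest.approx(22.686206088992975, rel=1e-12)
        assert res.alpha == pytest.approx(0.364166736840839, rel=1e-12)

    @given(log_rate, log_rate, log_rate)
    @settings(max_examples=60, deadline=None)
    def test_alpha_monotonicity(self, la, lkt, lp):
        k = cm.KineticConstants(ka=1e6, kd=0.1, ka_p=1e5, kd_p=0.05)
        a, kt, p = 10.0**la * 1e-9, 10.0**lkt, 10.0**lp * 1e-6
        base = cm.rebinding_factor_alpha(k, kt, p, a).alpha
        assert 0 < base <= 1
        # increasing A and kt raise alpha; increasing P lowers it
        assert cm.rebinding_factor_alpha(k, kt, p, 2 * a).alpha >= base
        assert cm.rebinding_factor_alpha(k, 2 * kt, p, a).alpha >= base
        assert cm.rebinding_factor_alpha(k, kt, 2 * p, a).alpha <= base

    def test_koff_limits(self):
        k = cm.KineticConstants(ka=1e8, kd=1e-6, ka_p=1e6, kd_p=0.05)
        # full inhibition: koff -> kd'
        full = cm.rebinding_factor_alpha(k, 100.0, 1e-3, 10.0)
        assert cm.observed_koff(k.kd_p, full.alpha) == pytest.approx(0.05, rel=1e-3)
        # blank: koff = kd' kt/(kt + ka'P)
        blank = cm.rebinding_factor_alpha(k, 100.0, 1e-3, 0.0)
        assert cm.observed_koff(k.kd_p, blank.alpha) == pytest.approx(
            0.05 * 100.0 / (100.0 + 1e3), rel=1e-12)


class TestRebindingResponse:
    def test_initial_and_unit_decay(self):
        assert cm.rebinding_response(118.0, 0.075, 0.5, 0.0) == 118.0
        assert cm.rebinding_response(1.0, 2.0, 1.0, 0.5) == pytest.approx(1 / math.e)

    def test_frozen_decay_value(self):
        assert cm.rebinding_response(118.0, 0.075, 1.0, 10.0) == pytest.approx(
            55.73925322343973, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(cm.InvalidParameterError):
            cm.rebinding_response(10.0, 0.05, 1.0, -1.0)

    def test_monotone_nonincreasing(self):
        r = cm.rebinding_response(100.0, 0.05, 0.3, np.linspace(0, 100, 200))
        assert np.all(np.diff(r) <= 0)


class TestConversions:
    def test_saturation_response_of_1mM_probe(self):
        assert cm.rmax_from_probe_concentration(1e-3, 100.0, 30000.0) \
            == pytest.approx(3000.0)

    def test_probe_concentration_from_loading_fit(self):
        assert cm.probe_concentration_from_rmax(1025.0, 100.0, 22000.0) \
            == pytest.approx(4.659090909090909e-4, rel=1e-12)

    @given(st.floats(1.0, 1e5), st.floats(1e3, 1e6), st.floats(10.0, 1e4))
    @settings(max_examples=40, deadline=None)
    def test_round_trip(self, rmax, mr_b, g):
        p = cm.probe_concentration_from_rmax(rmax, g, mr_b)
        assert cm.rmax_from_probe_concentration(p, g, mr_b) == pytest.approx(
            rmax, rel=1e-14)

    def test_diffusion_rescaling(self):
        assert cm.diffusion_rescale_ka(8.0, 8.0, 1.0) == pytest.approx(4.0)
        assert cm.diffusion_rescale_ka(5.0, 737.0, 737.0) == 5.0
        # linear mass-ratio variant
        assert cm.diffusion_rescale_ka(2.76e6, 22000.0, 737.0, exponent=1.0) \
            == pytest.approx(2.76e6 * 737 / 22000, rel=1e-12)

    def test_kt_response_scaling(self):
        assert cm.kt_response_scaled(1e-5, 30000.0) == pytest.approx(3e8)

    def test_flow_scaling_round_trip(self):
        kt = cm.kt_flow_scaling(100.0, 0.1)
        assert cm.kt_flow_scaling(100.0, 0.8) / kt == pytest.approx(2.0)
        assert cm.tc_from_kt(kt, 0.1) == pytest.approx(100.0, rel=1e-14)


class TestRebindingProbability:
    def test_unit_exponent(self):
        hgel = 1e-7
        d, pr = cm.rebinding_probability(hgel, hgel**2 * 40.0, 1.0, 40.0, 1.0)
        assert d == pytest.approx(hgel)
        assert pr == pytest.approx(1 - 1 / math.e)

    def test_hand_arithmetic(self):
        d, pr = cm.rebinding_probability(200e-9, 1e-10, 0.4, 40.0, 1.0)
        assert d == pytest.approx(1e-6, rel=1e-12)
        assert pr == pytest.approx(1 - math.exp(-0.2), rel=1e-12)

    def test_strong_flux_limit(self):
        _, pr = cm.rebinding_probability(200e-9, 1e-10, 0.4, 1e12, 1.0)
        assert pr > 0.999


class TestKtFromBlank:
    def test_half_rate_inversion(self):
        # koff = kd'/2 -> kt = ka' P
        assert cm.kt_from_blank_koff(0.025, 0.05, 1e6, 1e-3) == pytest.approx(1e3)

    def test_no_rebinding_sentinel(self):
        assert math.isinf(cm.kt_from_blank_koff(0.06, 0.05, 1e6, 1e-3))


def test_kinetic_constants_reject_negative_rates():
    with pytest.raises(cm.InvalidParameterError):
        cm.KineticConstants(ka=-1.0)


def test_transport_spec_invariants():
    spec = cm.TransportSpec(kt=20.0)
    assert spec.tau * spec.kt == pytest.approx(1.0)
    with pytest.raises(cm.InvalidParameterError):
        cm.TransportSpec(Kpart=1.5)
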