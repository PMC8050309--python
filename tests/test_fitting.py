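"""Fitting engine: preprocessing, parameter roles, self-consistency, stats."""

import numpy as np
import pytest

from rebindkin.core_models import (
    KineticConstants,
    probe_concentration_from_rmax,
    rebinding_factor_alpha,
    rebinding_response,
)
from rebindkin.fitting import (
    Parameter,
    chi2_percent,
    double_reference,
    estimate_rmax_loading,
    fit_curveset,
    goodness_stats,
    time_normalize_at_threshold,
)
from rebindkin.sensorgram import Sensorgram

# fit-derived constants of the workflow probe/target pair, used to build
# self-consistent synthetic curve sets
KA, KD, KA_P, KD_P = 3.07e6, 0.125, 8.5e4, 0.075
KT, RMAX, MR_B = 10.55, 1025.0, 22000.0
A_SERIES = (0.0, 0.016e-6, 0.6e-6, 4e-6)


def rebinding_curveset(r0=118.0, duration=120.0, noise=0.0, seed=0):
    p = probe_concentration_from_rmax(RMAX, 100.0, MR_B)
    k = KineticConstants(ka=KA, kd=KD, ka_p=KA_P, kd_p=KD_P)
    t = np.arange(0.0, duration + 1.0)
    cols, metas = [], []
    for a in A_SERIES:
        alpha, _, _ = rebinding_factor_alpha(k, KT, p, a)
        cols.append(rebinding_response(r0, KD_P, alpha, t))
        metas.append({"A": a, "Mr_B": MR_B})
    resp = np.column_stack(cols)
    if noise:
        resp = resp + np.random.default_rng(seed).normal(0, noise, resp.shape)
    return Sensorgram(t, resp, metas)


class TestPreprocessing:
    def test_double_reference_identity_and_zero(self):
        t = np.arange(0.0, 50.0)
        act = Sensorgram(t, 10 * np.exp(-0.05 * t))
        zero = Sensorgram(t, np.zeros_like(t))
        out = double_reference(act, zero, zero)
        assert np.allclose(out.response, act.response)
        out2 = double_reference(act, act, zero)
        assert np.allclose(out2.response, 0.0)

    def test_double_reference_removes_drift(self):
        t = np.arange(0.0, 100.0)
        signal = 50 * np.exp(-0.03 * t)
        drift = 0.02 * t + 1.5
        act = Sensorgram(t, signal + drift)
        ref = Sensorgram(t, drift)
        blank = Sensorgram(t, np.zeros_like(t))
        out = double_reference(act, ref, blank)
        assert np.allclose(out.response[:, 0], signal, atol=1e-12)

    def test_double_reference_requires_overlap(self):
        t = np.arange(0.0, 50.0)
        act = Sensorgram(t, np.ones_like(t))
        short = Sensorgram(t[:10], np.ones(10))
        with pytest.raises(ValueError):
            double_reference(act, short, act)

    def test_time_normalize_crossing_time(self):
        t = np.arange(0.0, 120.0)
        sg = Sensorgram(t, 200.0 * np.exp(-0.05 * t))
        out = time_normalize_at_threshold(sg, 118.0)
        # closed-form crossing at ln(200/118)/0.05 = 10.5527 s
        assert out.metadata[0]["t_cross"] == pytest.approx(10.5527, abs=0.02)
        assert out.response[0, 0] == pytest.approx(118.0, rel=1e-3)

    def test_time_normalize_aligns_replicates(self):
        t = np.arange(0.0, 200.0)
        cols = [r0 * np.exp(-0.04 * t) for r0 in (150.0, 200.0, 400.0)]
        sg = Sensorgram(t, np.column_stack(cols))
        out = time_normalize_at_threshold(sg, 118.0)
        assert out.n_curves == 3
        assert np.ptp(out.response[0, :]) < 0.05  # interpolation error only

    def test_curve_below_threshold_excluded(self):
        t = np.arange(0.0, 50.0)
        cols = np.column_stack([200 * np.exp(-0.05 * t), 50 * np.exp(-0.05 * t)])
        sg = Sensorgram(t, cols)
        with pytest.warns(UserWarning):
            out = time_normalize_at_threshold(sg, 118.0)
        assert out.n_curves == 1


class TestRebindingGlobalFit:
    def test_noiseless_self_consistency_recovers_constants(self):
        """Noiseless curves generated from the rebinding model return the
        generating ka and kt to at least 4 significant figures."""
        cs = rebinding_curveset()
        params = [
            Parameter("ka", 1e6, "global"),
            Parameter("kt", 30.0, "global"),
            Parameter("r0", np.full(4, 118.0), "local", log=False),
            Parameter("kd", KD, "fixed"),
            Parameter("ka_p", KA_P, "fixed"),
            Parameter("kd_p", KD_P, "fixed"),
            Parameter("rmax", RMAX, "fixed"),
        ]
        res = fit_curveset(cs, "rebinding", params)
        assert res.converged
        assert res["ka"].value == pytest.approx(KA, rel=1e-4)
        assert res["kt"].value == pytest.approx(KT, rel=1e-4)
        assert res.chi2_pct < 1e-6
        # perfect data: CI fraction is essentially zero
        assert res["ka"].ci_fraction < 1e-6

    def test_blank_curve_pins_kt(self):
        cs = rebinding_curveset().select([0])  # A = 0 only
        params = [
            Parameter("kt", 100.0, "global"),
            Parameter("r0", 118.0, "local", log=False),
            Parameter("kd", KD, "fixed"), Parameter("ka", KA, "fixed"),
            Parameter("ka_p", KA_P, "fixed"), Parameter("kd_p", KD_P, "fixed"),
            Parameter("rmax", RMAX, "fixed"),
        ]
        res = fit_curveset(cs, "rebinding", params)
        assert res["kt"].value == pytest.approx(KT, rel=1e-4)

    def test_flow_rate_tie_through_tc(self):
        """Curves at three flow velocities sharing kt = tc*u^(1/3) recover tc."""
        tc_true = 800.0
        p = probe_concentration_from_rmax(3000.0)
        k = KineticConstants(ka=1e6, kd=10.0, ka_p=1e6, kd_p=0.05)
        t = np.arange(0.0, 200.0)
        cols, metas = [], []
        for u in (0.1, 0.01, 0.001):
            kt = tc_true * u ** (1 / 3)
            alpha, _, _ = rebinding_factor_alpha(k, kt, p, 1e-3)
            cols.append(rebinding_response(300.0, 0.05, alpha, t))
            metas.append({"A": 1e-3, "flow_velocity": u})
        cs = Sensorgram(t, np.column_stack(cols), metas)
        params = [
            Parameter("tc", 300.0, "global"),
            Parameter("ka", 1e6, "fixed"), Parameter("kd", 10.0, "fixed"),
            Parameter("r0", np.full(3, 300.0), "fixed"),
            Parameter("ka_p", 1e6, "fixed"), Parameter("kd_p", 0.05, "fixed"),
            Parameter("rmax", 3000.0, "fixed"),
        ]
        res = fit_curveset(cs, "rebinding", params)
        assert res["tc"].value == pytest.approx(tc_true, rel=1e-6)

    def test_global_vs_local_sse_contract(self):
        """Freeing a truly shared parameter per curve never increases SSE."""
        cs = rebinding_curveset(noise=0.05, seed=3)
        base = [
            Parameter("ka", 1e6, "global"),
            Parameter("kt", 30.0, "global"),
            Parameter("r0", np.full(4, 118.0), "local", log=False),
            Parameter("kd", KD, "fixed"), Parameter("ka_p", KA_P, "fixed"),
            Parameter("kd_p", KD_P, "fixed"), Parameter("rmax", RMAX, "fixed"),
        ]
        res_g = fit_curveset(cs, "rebinding", base)
        local = [Parameter("kt", 30.0, "local") if p.name == "kt" else p
                 for p in base]
        res_l = fit_curveset(cs, "rebinding", local)
        assert res_l.sse <= res_g.sse * (1 + 1e-8)

    def test_multistart_escapes_poor_start(self):
        cs = rebinding_curveset()
        params = [
            Parameter("ka", 1e2, "global"),
            Parameter("kt", KT, "fixed"),
            Parameter("r0", np.full(4, 118.0), "fixed"),
            Parameter("kd", KD, "fixed"), Parameter("ka_p", KA_P, "fixed"),
            Parameter("kd_p", KD_P, "fixed"), Parameter("rmax", RMAX, "fixed"),
        ]
        starts = [{"ka": 10.0**e} for e in (3, 5, 7, 9)]
        res = fit_curveset(cs, "rebinding", params, multistart=starts)
        assert res["ka"].value == pytest.approx(KA, rel=1e-3)

    def test_nan_padding_defines_per_curve_windows(self):
        cs = rebinding_curveset()
        resp = cs.response.copy()
        resp[60:, 1] = np.nan  # truncate one curve
        cs2 = Sensorgram(cs.time, resp, cs.metadata)
        params = [
            Parameter("ka", 1e6, "global"),
            Parameter("kt", 30.0, "global"),
            Parameter("r0", np.full(4, 118.0), "local", log=False),
            Parameter("kd", KD, "fixed"), Parameter("ka_p", KA_P, "fixed"),
            Parameter("kd_p", KD_P, "fixed"), Parameter("rmax", RMAX, "fixed"),
        ]
        res = fit_curveset(cs2, "rebinding", params)
        assert res["ka"].value == pytest.approx(KA, rel=1e-4)
        assert res.n_obs == np.isfinite(resp).sum()


class TestTwoCompartmentModel:
    def test_self_fit_ideal_limit(self):
        from rebindkin.ode_simulator import InjectionProgram, simulate_two_compartment

        k = KineticConstants(ka_p=5e5, kd_p=0.02)
        prog = InjectionProgram.pulse(120.0, 1e-7, 120.0)
        sg = simulate_two_compartment(k, np.inf, 50.0, prog)
        sg.metadata[0].update(conc=1e-7, contact_time=120.0)
        params = [
            Parameter("ka_p", 1e5, "global"),
            Parameter("kd_p", 0.1, "global"),
            Parameter("rmax", 50.0, "fixed"),
            Parameter("kt", 1e9, "fixed"),  # effectively transport-free
        ]
        res = fit_curveset(sg, "two_compartment_1to1", params)
        assert res["ka_p"].value == pytest.approx(5e5, rel=5e-3)
        assert res["kd_p"].value == pytest.approx(0.02, rel=5e-3)
        assert res.chi2_pct < 5.0


class TestLoadingFit:
    def make_loading(self, noise=0.0, seed=0, n=1):
        # association + dissociation: the decay phase pins kd, so Rmax is
        # identifiable from a single loading concentration
        ka, kd, rmax, conc, tc = 2e5, 0.01, 1025.0, 500e-9, 60.0
        t = np.arange(0.0, 180.0)
        kobs = ka * conc + kd
        req = rmax * conc / (conc + kd / ka)
        y = np.where(t <= tc,
                     req * (1 - np.exp(-kobs * t)),
                     req * (1 - np.exp(-kobs * tc))
                     * np.exp(-kd * np.clip(t - tc, 0, None)))
        cols = np.column_stack([y] * n)
        if noise:
            cols = cols + np.random.default_rng(seed).normal(0, noise, cols.shape)
        return Sensorgram(t, cols, [{"conc": conc, "contact_time": tc}] * n), rmax

    def test_rmax_recovered_within_1pct(self):
        sg, rmax = self.make_loading()
        res = estimate_rmax_loading(sg)
        assert res["rmax"].value == pytest.approx(rmax, rel=0.01)

    def test_replicate_loadings_give_precise_rmax(self):
        sg, rmax = self.make_loading(noise=0.03, seed=7, n=8)
        res = estimate_rmax_loading(sg)
        assert res["rmax"].value == pytest.approx(rmax, rel=0.01)
        assert res["rmax"].se < 0.01 * rmax


class TestGoodnessStats:
    def test_zero_residuals(self):
        assert chi2_percent(np.zeros((10, 2)), np.ones((10, 2)) * 50) == 0.0

    def test_unit_residuals_over_max_100(self):
        resid = np.ones((25, 4))
        resp = np.full((25, 4), 37.0)
        resp[3, 2] = 100.0
        assert chi2_percent(resid, resp) == pytest.approx(1.0)

    def test_literal_square_variant(self):
        resid = np.full((10, 1), 2.0)
        resp = np.full((10, 1), 100.0)
        assert chi2_percent(resid, resp, literal_square=True) == pytest.approx(4.0)

    def test_goodness_stats_reports_free_parameters_only(self):
        cs = rebinding_curveset(noise=0.03, seed=1)
        params = [
            Parameter("ka", 1e6, "global"),
            Parameter("kt", 30.0, "global"),
            Parameter("r0", np.full(4, 118.0), "local", log=False),
            Parameter("kd", KD, "fixed"), Parameter("ka_p", KA_P, "fixed"),
            Parameter("kd_p", KD_P, "fixed"), Parameter("rmax", RMAX, "fixed"),
        ]
        res = fit_curveset(cs, "rebinding", params)
        stats = goodness_stats(res)
        assert set(stats["parameters"]) == {"ka", "kt", "r0"}
        assert stats["chi2_pct"] < 5.0  # the fit-quality threshold
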