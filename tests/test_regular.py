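"""Regular-spiking escape probabilities, divergence bounds and the
burst/tonic-firing conditions."""

import math

import numpy as np
import pytest

import spikestab as ss
from spikestab.regular import geometric_lhs
from spikestab.stability import _QRTables


class TestPRegularDivergence:
    def test_refractory_only_never_escapes(self, refractory_only):
        # p(x,k) = 1 - exp(-c (x - tau_ref)) is constant in k, never -> 1
        for x in (0.01, 0.05, 0.15):
            assert ss.p_regular_divergence(refractory_only, 4.95, x) == 0.0

    def test_refractory_only_interval_probability_closed_form(
            self, refractory_only):
        # p(x, k) = 1 - exp(-c (x - tau_ref)) for every k: the pre-history
        # gamma tail vanishes beyond tau_ref and no excitation accumulates
        from spikestab.regular import p_interval_sequence
        x = 0.05
        ps = p_interval_sequence(refractory_only, 4.95, x, 6)
        expected = -math.expm1(-5.0 * (x - 0.002))
        assert np.allclose(ps, expected, rtol=2e-2)
        assert np.allclose(ps, ps[0], rtol=1e-9)

    def test_first_interval_uses_only_prehistory_term(self, exp_fragile):
        # p(x, 1) = 1 - exp(-int_0^x lambda_reg) with only the a0
        # pre-history term active before the first regular spike
        from spikestab.regular import p_interval_sequence
        a0, x = 5.6, 0.01
        tab = _QRTables(exp_fragile)
        u = np.linspace(0.0, x, 5000)
        eta0 = np.where(u < exp_fragile.tau_ref, -np.inf,
                        exp_fragile.kernel.parametric(u))
        lam = np.exp(exp_fragile.I0 + eta0 + a0 * tab.G_at(u))
        p1_fine = -math.expm1(-np.trapezoid(lam, u))
        p1 = p_interval_sequence(exp_fragile, a0, x, 1)[0]
        assert p1 == pytest.approx(p1_fine, rel=5e-3)

    def test_accumulating_excitation_increases_p(self):
        # strongly self-exciting kernel: p(x,k) grows with k near tau_ref
        from spikestab.regular import p_interval_sequence
        m = ss.HawkesModel.from_rate(5.0, ss.SingleExpKernel(J=2.0, tau=0.02))
        a0 = 7.38
        x = m.tau_ref * 1.2
        ps = p_interval_sequence(m, a0, x, 5)
        assert np.all(np.diff(ps) > 0)
        assert ss.p_regular_divergence(m, a0, x) > 0.0

    def test_out_of_range_x_rejected(self, exp_fragile):
        with pytest.raises(ValueError):
            ss.p_regular_divergence(exp_fragile, 5.6, 0.001)
        with pytest.raises(ValueError):
            ss.p_regular_divergence(exp_fragile, 5.6, 1.0)

    def test_probability_bounds(self, exp_fragile):
        for x in (0.0021, 0.0025, 0.01, 0.05):
            p = ss.p_regular_divergence(exp_fragile, 5.6, x)
            assert 0.0 <= p <= 1.0


class TestPredictDivergenceBound:
    def test_refractory_only_unbounded(self, refractory_only):
        res = ss.predict_divergence_bound(refractory_only, 4.95)
        assert res.p_reg_max == 0.0
        assert res.t_div_upper == np.inf

    def test_stable_model_has_negligible_escape(self, exp_stable):
        res = ss.predict_divergence_bound(exp_stable, 4.616)
        assert res.p_reg_max < 1e-3

    def test_fragile_bound_is_finite_and_consistent(self, exp_fragile):
        rep = ss.classify(exp_fragile, t_div_bound=False)
        a0 = min(fp.a0_hat for fp in rep.fixed_points if fp.stable)
        res = ss.predict_divergence_bound(exp_fragile, a0)
        assert np.isfinite(res.t_div_upper)
        assert res.t_div_upper == pytest.approx(
            1.0 / (a0 * res.p_reg_max), rel=1e-12)
        assert exp_fragile.tau_ref <= res.x_star <= 1.0 / a0

    def test_x_grid_density_convergence(self):
        # deep in the fragile regime the maximized bound is insensitive to
        # the x-grid density
        m = ss.HawkesModel.from_rate(5.0, ss.SingleExpKernel(J=1.5, tau=0.02))
        rep = ss.classify(m, t_div_bound=False)
        a0 = min(fp.a0_hat for fp in rep.fixed_points if fp.stable)
        r1 = ss.predict_divergence_bound(m, a0, n_x=200)
        r2 = ss.predict_divergence_bound(m, a0, n_x=400)
        assert abs(r2.t_div_upper - r1.t_div_upper) / r1.t_div_upper < 0.05

    def test_scaling_up_excitation_does_not_decrease_escape(self):
        # one-parameter excitatory family: p_reg_max monotone in J
        ps = []
        for J in (1.3, 1.6, 1.9):
            m = ss.HawkesModel.from_rate(5.0, ss.SingleExpKernel(J=J,
                                                                 tau=0.02))
            rep = ss.classify(m, t_div_bound=False)
            a0 = min(fp.a0_hat for fp in rep.fixed_points if fp.stable)
            ps.append(ss.predict_divergence_bound(m, a0).p_reg_max)
        assert ps[0] <= ps[1] <= ps[2]


class TestRegularLimitCondition:
    def test_flat_kernel_reduces_to_closed_form(self):
        # eta = 0 beyond the refractory period: condition iff
        # c (x - tau_ref) >= 1 iff x >= tau_ref + 1/c
        m = ss.HawkesModel.from_rate(5.0, ss.SingleExpKernel(J=0.0, tau=0.02))
        x_crit = 0.002 + 1.0 / 5.0
        assert ss.regular_limit_condition(m, x_crit + 1e-6)
        assert not ss.regular_limit_condition(m, x_crit - 1e-6)

    def test_geometric_closed_form_vs_partial_sums(self, rng):
        # closed form of the double-exponential series equals direct
        # summation for 100 random parameter tuples to 1e-10 relative
        for _ in range(100):
            J_r = float(rng.uniform(-11, 11))
            J_a = float(rng.uniform(-3, 3))
            tau_r = float(rng.uniform(0.005, 0.05))
            tau_a = float(rng.uniform(0.05, 0.3))
            x = float(rng.uniform(0.0021, 0.05))
            K = int(rng.integers(1, 2000))
            closed = (geometric_lhs(J_r, tau_r, x, K)
                      + geometric_lhs(J_a, tau_a, x, K))
            ks = np.arange(1, K + 1)
            direct = np.sum(J_r * np.exp(-ks * x / tau_r)
                            + J_a * np.exp(-ks * x / tau_a))
            assert closed == pytest.approx(direct, rel=1e-10, abs=1e-12)

    def test_infinite_sum_limit_of_partial_sums(self, rng):
        J_r, tau_r, J_a, tau_a, x = 2.0, 0.02, -1.0, 0.1, 0.01
        inf_closed = (geometric_lhs(J_r, tau_r, x, np.inf)
                      + geometric_lhs(J_a, tau_a, x, np.inf))
        big = (geometric_lhs(J_r, tau_r, x, 100_000)
               + geometric_lhs(J_a, tau_a, x, 100_000))
        assert inf_closed == pytest.approx(big, rel=1e-10)

    def test_divergent_excitatory_holds_near_tau_ref(self, exp_divergent):
        # LHS ~ J tau / x blows up as x -> tau_ref while RHS grows only
        # logarithmically
        assert ss.regular_limit_condition(exp_divergent,
                                          exp_divergent.tau_ref + 1e-5)

    def test_x_at_or_below_tau_ref_rejected(self, exp_divergent):
        with pytest.raises(ValueError):
            ss.regular_limit_condition(exp_divergent, 0.002)


class TestBurstDuration:
    def test_sustainable_kernel_reports_infinite_burst(self, exp_divergent):
        res = ss.burst_duration(exp_divergent)
        assert res.sustainable
        assert res.k_max == np.inf and res.burst_duration == np.inf

    def test_flat_kernel_sustainable_iff_rate_sufficient(self):
        # c (x - tau_ref) >= 1 at the probe interval
        m_hi = ss.HawkesModel.from_rate(5000.0,
                                        ss.SingleExpKernel(J=0.0, tau=0.02))
        res = ss.burst_duration(m_hi, probe_rate_fraction=0.9)
        assert res.sustainable and res.k_max == np.inf

    def test_intermittent_burst_corner_finite_kmax(self):
        # strong fast excitation with strong slow adaptation: QR predicts
        # divergent but tonic firing cannot be sustained -> finite bursts
        m = ss.HawkesModel.from_rate(5.0, ss.DoubleExpKernel(
            J_r=10.0, tau_r=0.02, J_a=-3.0, tau_a=0.1))
        assert ss.classify(m, t_div_bound=False).label == "divergent"
        res = ss.burst_duration(m)
        assert not res.sustainable
        assert 0 < res.k_max < np.inf
        assert res.burst_duration == res.k_max * res.probe_interval
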