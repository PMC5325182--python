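"""Time-rescaling, KS calibration, predictive power, ISI statistics and
correlation functions."""

import numpy as np
import pytest
from scipy import stats

import spikestab as ss


@pytest.fixture(scope="module")
def gof_model():
    """A stable model firing around 19 s^-1 (many spikes per unit time)."""
    return ss.HawkesModel.from_rate(
        20.0, ss.SingleExpKernel(J=-0.5, tau=0.02))


class TestTimeRescale:
    def test_homogeneous_poisson_exact(self, poisson):
        tr = ss.simulate(poisson, ss.SimulationConfig(
            duration=100.0, n_replicates=1, seed=41))[0]
        z = ss.time_rescale(poisson, tr)
        assert np.allclose(z, 5.0 * tr.isis(), rtol=1e-9, atol=1e-9)

    def test_mean_z_near_one_for_true_model(self, gof_model):
        tr = ss.simulate(gof_model, ss.SimulationConfig(
            duration=300.0, n_replicates=1, seed=42))[0]
        z = ss.time_rescale(gof_model, tr)
        assert abs(z.mean() - 1.0) < 3.0 / np.sqrt(z.size)

    def test_misspecified_rate_detected(self, gof_model):
        tr = ss.simulate(gof_model, ss.SimulationConfig(
            duration=300.0, n_replicates=1, seed=43))[0]
        wrong = ss.HawkesModel.from_rate(
            2.0 * gof_model.c, gof_model.kernel)
        z = ss.time_rescale(wrong, tr)
        assert not ss.ks_test_exp1(z).passed

    def test_empty_train_rejected(self, poisson):
        with pytest.raises(ValueError):
            ss.time_rescale(poisson,
                            ss.SpikeTrain(times=np.array([]), duration=1.0))


class TestKSExp1:
    def test_exact_quantiles_give_tiny_statistic(self):
        q = (np.arange(1, 1001) - 0.5) / 1000
        z = -np.log1p(-q)
        res = ss.ks_test_exp1(z)
        assert res.statistic < 1e-3

    def test_point_mass_statistic(self):
        # all z = 1: D = max(1 - e^{-1}, e^{-1}) = 0.6321
        res = ss.ks_test_exp1(np.ones(50))
        assert res.statistic == pytest.approx(1.0 - np.exp(-1.0), abs=1e-6)
        assert not res.passed

    def test_calibrated_type_one_error(self, rng):
        # nominal 5 % level: rejection rate within [0.03, 0.07] over 1000
        # Exp(1) samples of size 500
        rejects = 0
        for _ in range(1000):
            z = rng.exponential(1.0, 500)
            rejects += not ss.ks_test_exp1(z).passed
        assert 30 <= rejects <= 70

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ss.ks_test_exp1(np.ones(5))


class TestPredictivePower:
    def test_constant_intensity_is_chance(self, poisson, gof_model):
        tr = ss.simulate(gof_model, ss.SimulationConfig(
            duration=100.0, n_replicates=1, seed=44))[0]
        assert ss.predictive_power(poisson, tr) == pytest.approx(0.0,
                                                                 abs=0.05)

    def test_oracle_indicator_is_perfect(self, gof_model):
        # rank bins by the spike indicator itself: AUC = 1, PP = 1
        tr = ss.simulate(gof_model, ss.SimulationConfig(
            duration=50.0, n_replicates=1, seed=45))[0]
        from sklearn.metrics import roc_auc_score
        delta = 1e-3
        n_bins = int(round(tr.duration / delta))
        y = np.zeros(n_bins)
        y[np.minimum((tr.times / delta).astype(int), n_bins - 1)] = 1
        assert 2 * roc_auc_score(y, y) - 1 == 1.0

    def test_true_model_beats_chance_and_reset_on_nonrenewal(self,
                                                            exp_fragile):
        # adaptation/excitation carries across spikes: the full-history
        # model predicts no worse than the reset (renewal) model on average
        m_full = ss.HawkesModel.from_rate(5.0, ss.DoubleExpKernel(
            J_r=1.0, tau_r=0.02, J_a=-1.0, tau_a=0.1))
        pps_full, pps_reset = [], []
        for seed in range(20):
            tr = ss.simulate(m_full, ss.SimulationConfig(
                duration=60.0, n_replicates=1, seed=seed,
                stop_on_divergence=True))[0]
            pps_full.append(ss.predictive_power(m_full, tr))
            lam_reset = _reset_intensity_grid(m_full, tr, 1e-3)
            from sklearn.metrics import roc_auc_score
            n_bins = lam_reset.size
            y = np.zeros(n_bins)
            y[np.minimum((tr.times / 1e-3).astype(int), n_bins - 1)] = 1
            pps_reset.append(2 * roc_auc_score(y, lam_reset) - 1)
        assert np.mean(pps_full) > 0.0
        assert np.mean(pps_full) >= np.mean(pps_reset) - 0.01

    def test_empty_test_set_rejected(self, poisson):
        with pytest.raises(ValueError):
            ss.predictive_power(
                poisson, ss.SpikeTrain(times=np.array([]), duration=1.0))


def _reset_intensity_grid(model, train, delta):
    """Renewal-model intensity on the bin grid (most recent spike only)."""
    n_bins = int(round(train.duration / delta))
    starts = np.arange(n_bins) * delta
    idx = np.searchsorted(train.times, starts, side="left") - 1
    lag = np.where(idx >= 0, starts - train.times[np.clip(idx, 0, None)],
                   np.inf)
    lam = np.where(
        np.isfinite(lag),
        model.phi(model.I0 + ss.eval_kernel(model.kernel, lag)),
        model.phi(model.I0) * np.ones_like(lag))
    return np.asarray(lam, dtype=float)


class TestIsiStatistics:
    def test_perfectly_regular_train_has_zero_lv(self):
        tr = ss.SpikeTrain(times=np.arange(0.01, 10.0, 0.01), duration=10.0)
        st_ = ss.isi_statistics(tr)
        assert st_.lv_mean == pytest.approx(0.0, abs=1e-12)

    def test_poisson_lv_near_one_and_logk_near_zero(self, poisson):
        tr = ss.simulate(poisson, ss.SimulationConfig(
            duration=2000.0, n_replicates=1, seed=46))[0]
        st_ = ss.isi_statistics(tr)
        n = st_.n_segments
        assert abs(st_.lv_mean - 1.0) < 3 * st_.lv_sd / np.sqrt(n)
        # ML Gamma shape on 20-ISI blocks is biased upward; compare to the
        # sampling distribution of the same estimator on true Exp draws
        rng = np.random.default_rng(460)
        ref = []
        for _ in range(400):
            block = rng.exponential(0.2, 20)
            shape, _, _ = stats.gamma.fit(block, floc=0.0)
            ref.append(np.log(shape))
        se = (np.std(ref) / np.sqrt(n)
              + np.std(ref) / np.sqrt(len(ref)))
        assert abs(st_.log_kappa_mean - np.mean(ref)) < 3 * se

    def test_gamma_renewal_shape_recovery(self, rng):
        # Gamma(4) renewal ISIs: recovered log kappa matches the sampling
        # mean of the block estimator at kappa=4, and clearly separates
        # from kappa=1
        kappa = 4.0
        isis = rng.gamma(kappa, 0.01, 4000)
        times = np.cumsum(isis)
        tr = ss.SpikeTrain(times=times, duration=times[-1] + 0.01)
        st_ = ss.isi_statistics(tr)
        ref = []
        for _ in range(400):
            block = rng.gamma(kappa, 0.01, 20)
            shape, _, _ = stats.gamma.fit(block, floc=0.0)
            ref.append(np.log(shape))
        se = (np.std(ref) / np.sqrt(st_.n_segments)
              + np.std(ref) / np.sqrt(len(ref)))
        assert abs(st_.log_kappa_mean - np.mean(ref)) < 3 * se
        assert st_.log_kappa_mean > np.log(2.0)

    def test_too_few_isis_rejected(self):
        tr = ss.SpikeTrain(times=np.linspace(0.1, 0.9, 10), duration=1.0)
        with pytest.raises(ValueError):
            ss.isi_statistics(tr)


class TestCorrelations:
    def test_poisson_autocorr_flat(self, poisson):
        tr = ss.simulate(poisson, ss.SimulationConfig(
            duration=1000.0, n_replicates=1, seed=47))[0]
        lags, ac, _, _ = ss.correlations(tr, max_lag_s=0.03, max_isi_lag=3)
        assert ac[0] == 1.0
        assert np.all(np.abs(ac[1:]) < 0.01)

    def test_renewal_simulation_has_no_serial_isi_corr(self, exp_fragile):
        tr = ss.simulate(exp_fragile, ss.SimulationConfig(
            duration=400.0, n_replicates=1, seed=48, reset_mode=True))[0]
        _, _, _, icorr = ss.correlations(tr, max_isi_lag=3)
        n = len(tr) - 1
        assert np.all(np.abs(icorr) < 3.0 / np.sqrt(n))

    def test_slow_adaptation_gives_negative_lag1_isi_corr(self):
        m = ss.HawkesModel.from_rate(20.0, ss.DoubleExpKernel(
            J_r=0.0, tau_r=0.02, J_a=-1.0, tau_a=0.2))
        tr = ss.simulate(m, ss.SimulationConfig(
            duration=400.0, n_replicates=1, seed=49))[0]
        _, _, _, icorr = ss.correlations(tr, max_isi_lag=2)
        assert icorr[0] < -3.0 / np.sqrt(len(tr) - 1)

    def test_too_few_isis_for_lag_rejected(self):
        tr = ss.SpikeTrain(times=np.array([0.1, 0.2, 0.3]), duration=1.0)
        with pytest.raises(ValueError):
            ss.correlations(tr, max_isi_lag=5)
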