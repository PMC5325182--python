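"""Goodness-of-fit battery for spiking point-process models.

Covers the time-rescaling Kolmogorov-Smirnov test, per-bin spike-prediction
ROC (predictive power PP = 2*AUC - 1), segment-wise inter-spike-interval
statistics (local variation lv, Gamma shape/scale), and spike-count /
serial-ISI correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .models import HawkesModel, SpikeTrain, intensity_on_grid

__all__ = [
    "KSResult",
    "IsiStats",
    "GofReport",
    "time_rescale",
    "ks_test_exp1",
    "predictive_power",
    "isi_statistics",
    "correlations",
    "gof_report",
]

#: ISIs per disjoint segment for the segment-wise statistics
SEGMENT_ISIS = 20


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    passed: bool  # p > 0.05


@dataclass(frozen=True)
class IsiStats:
    lv_mean: float
    lv_sd: float
    log_kappa_mean: float
    log_kappa_sd: float
    log_alpha_mean: float
    log_alpha_sd: float
    n_segments: int
    n_gamma_dropped: int  # segments where the Gamma ML fit failed


@dataclass(frozen=True)
class GofReport:
    ks: KSResult
    predictive_power: float
    bits_per_s: Optional[float]
    isi: Optional[IsiStats]
    autocorr_lags: np.ndarray
    autocorr: np.ndarray
    serial_isi_lags: np.ndarray
    serial_isi_corr: np.ndarray


def time_rescale(model: HawkesModel, train: SpikeTrain,
                 dt: float = 2e-4) -> np.ndarray:
    """Rescaled inter-spike intervals z_k = int_{t_{k-1}}^{t_k} lambda du.

    The integral uses the same piecewise-constant discretization as the
    likelihood and the simulator (intensity from history strictly before
    each bin start). Under the true model the z_k are i.i.d. Exp(1).
    """
    if len(train) < 2:
        raise ValueError("need at least two spikes to rescale intervals")
    n_bins = int(np.ceil(train.duration / dt))
    lam = intensity_on_grid(model, train, dt, n_bins=n_bins)
    edges = np.arange(n_bins + 1) * dt
    cum = np.concatenate([[0.0], np.cumsum(lam * dt)])
    z_at_spikes = np.interp(train.times, edges, cum)
    return np.diff(z_at_spikes)


def ks_test_exp1(z: np.ndarray) -> KSResult:
    """One-sample KS test of rescaled intervals against Exp(1).

    Transforms u = 1 - exp(-z) and tests against Uniform(0, 1) with the
    asymptotic Kolmogorov distribution; pass means p > 0.05.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 10:
        raise ValueError("need at least 10 rescaled intervals")
    u = -np.expm1(-z)
    res = stats.kstest(u, "uniform", mode="asymp")
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    passed=bool(res.pvalue > 0.05))


def predictive_power(model: HawkesModel, test_train: SpikeTrain,
                     delta: float = 1e-3) -> float:
    """PP = 2*AUC - 1 for predicting spike occupancy of Delta bins.

    Bins are ranked by the conditional intensity given the observed
    history; AUC is the area under the ROC curve of that ranking against
    the actual spike indicator.
    """
    if len(test_train) == 0:
        raise ValueError("test train has no spikes")
    n_bins = int(np.round(test_train.duration / delta))
    lam = intensity_on_grid(model, test_train, delta, n_bins=n_bins)
    idx = np.minimum((test_train.times / delta).astype(int), n_bins - 1)
    y = np.zeros(n_bins, dtype=int)
    y[idx] = 1
    if y.all():
        raise ValueError("every bin contains a spike; ROC undefined")
    auc = roc_auc_score(y, lam)
    return float(2.0 * auc - 1.0)


def _local_variation(isis: np.ndarray) -> float:
    """lv = 3/(n-1) * sum ((d_i - d_{i+1}) / (d_i + d_{i+1}))^2.

    0 for perfectly regular firing, approximately 1 for Poisson firing.
    """
    d0, d1 = isis[:-1], isis[1:]
    r = (d0 - d1) / (d0 + d1)
    return float(3.0 * np.mean(r * r))


def isi_statistics(train: SpikeTrain,
                   segment: int = SEGMENT_ISIS) -> IsiStats:
    """Segment-wise ISI statistics over disjoint blocks of 20 ISIs.

    Per block: local variation lv and the ML Gamma fit (shape kappa, scale
    alpha, both in log). Reported as mean +/- sd across blocks; blocks
    where the Gamma fit fails are dropped from the Gamma statistics and
    counted.
    """
    isis = train.isis()
    n_seg = isis.size // segment
    if n_seg < 1:
        raise ValueError(f"need at least {segment} ISIs")
    lvs, log_k, log_a = [], [], []
    dropped = 0
    for i in range(n_seg):
        block = isis[i * segment:(i + 1) * segment]
        lvs.append(_local_variation(block))
        try:
            with np.errstate(all="ignore"):
                shape, _, scale = stats.gamma.fit(block, floc=0.0)
            if not (np.isfinite(shape) and shape > 0 and scale > 0):
                raise ValueError
            log_k.append(np.log(shape))
            log_a.append(np.log(scale))
        except Exception:
            dropped += 1
    log_k = np.asarray(log_k)
    log_a = np.asarray(log_a)
    return IsiStats(
        lv_mean=float(np.mean(lvs)), lv_sd=float(np.std(lvs, ddof=1)) if
        len(lvs) > 1 else 0.0,
        log_kappa_mean=float(np.mean(log_k)) if log_k.size else np.nan,
        log_kappa_sd=float(np.std(log_k, ddof=1)) if log_k.size > 1 else 0.0,
        log_alpha_mean=float(np.mean(log_a)) if log_a.size else np.nan,
        log_alpha_sd=float(np.std(log_a, ddof=1)) if log_a.size > 1 else 0.0,
        n_segments=n_seg, n_gamma_dropped=dropped)


def correlations(train: SpikeTrain, max_lag_s: float = 0.05,
                 max_isi_lag: int = 5, bin_width: float = 1e-3,
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spike-count autocorrelation and serial ISI correlations.

    Returns (lags_s, autocorr, isi_lags, isi_corr): the mean-subtracted
    autocorrelation of 1-ms binned counts normalized to 1 at lag zero, and
    the Pearson correlation of (ISI_k, ISI_{k+j}) for j = 1..max_isi_lag.
    """
    if len(train) == 0:
        raise ValueError("empty spike train")
    n_bins = int(np.round(train.duration / bin_width))
    idx = np.minimum((train.times / bin_width).astype(int), n_bins - 1)
    x = np.bincount(idx, minlength=n_bins).astype(float)
    x -= x.mean()
    n_lag = int(np.round(max_lag_s / bin_width))
    denom = float(x @ x)
    ac = np.array([1.0 if l == 0 else float(x[:-l] @ x[l:]) / denom
                   for l in range(n_lag + 1)])
    lags = np.arange(n_lag + 1) * bin_width
    isis = train.isis()
    if isis.size < max_isi_lag + 2:
        raise ValueError("too few ISIs for the requested serial-ISI lag")
    isi_lags = np.arange(1, max_isi_lag + 1)
    isi_corr = np.array([
        float(np.corrcoef(isis[:-j], isis[j:])[0, 1]) for j in isi_lags])
    return lags, ac, isi_lags, isi_corr


def gof_report(model: HawkesModel, test_train: SpikeTrain,
               delta: float = 1e-3, rescale_dt: float = 2e-4,
               bits_per_s: Optional[float] = None,
               max_lag_s: float = 0.05, max_isi_lag: int = 5) -> GofReport:
    """Run the full battery against one held-out spike train."""
    z = time_rescale(model, test_train, dt=rescale_dt)
    ks = ks_test_exp1(z)
    pp = predictive_power(model, test_train, delta=delta)
    try:
        isi = isi_statistics(test_train)
    except ValueError:
        isi = None
    lags, ac, ilags, icorr = correlations(test_train, max_lag_s=max_lag_s,
                                          max_isi_lag=max_isi_lag)
    return GofReport(ks=ks, predictive_power=pp, bits_per_s=bits_per_s,
                     isi=isi, autocorr_lags=lags, autocorr=ac,
                     serial_isi_lags=ilags, serial_isi_corr=icorr)
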