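"""Model definitions: spike-history kernels, nonlinearities, spike trains,
and the conditional intensity function of the nonlinear Hawkes process.

The conditional intensity is

    lambda(t | H_t) = phi( I0 + sum_k eta(t - t_k) ),

where eta(s) is a causal spike-history kernel that equals -inf during the
absolute refractory period [0, tau_ref) so that exp(eta) = 0 there exactly,
and phi is a non-negative nonlinearity (exponential by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .basis import RaisedCosineBasis

__all__ = [
    "RefractorySpec",
    "SingleExpKernel",
    "DoubleExpKernel",
    "BasisKernel",
    "HistoryKernel",
    "Nonlinearity",
    "EXPONENTIAL",
    "LINEAR_RECTIFIER",
    "SOFTPLUS",
    "HawkesModel",
    "SpikeTrain",
    "eval_kernel",
    "conditional_intensity",
    "reset_conditional_intensity",
    "intensity_on_grid",
]

#: Kernel values below this magnitude are treated as numerically zero when
#: bounding history sums and integrals.
KERNEL_CUTOFF = 1e-8


@dataclass(frozen=True)
class RefractorySpec:
    """Absolute refractory period: eta(s) = -inf for 0 <= s < tau_ref.

    The log-modulation during the refractory period is a true ``-inf`` (so
    ``exp`` of it is exactly 0 in all downstream arithmetic), rather than a
    large negative surrogate. ``tau_ref = 0`` encodes the absence of an
    absolute refractory period (the rate is then unbounded and the
    fixed-point classification is undefined).
    """

    tau_ref: float = 0.002

    def __post_init__(self) -> None:
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")

    @property
    def j_ref(self) -> float:
        return -np.inf


@dataclass(frozen=True)
class SingleExpKernel:
    """eta(s) = J * exp(-s / tau) for s >= tau_ref."""

    J: float
    tau: float
    refractory: RefractorySpec = field(default_factory=RefractorySpec)

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    def parametric(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.J * np.exp(-s / self.tau)

    @property
    def support_end(self) -> float:
        if self.J == 0.0:
            return self.refractory.tau_ref
        return max(self.refractory.tau_ref,
                   self.tau * np.log(abs(self.J) / KERNEL_CUTOFF))


@dataclass(frozen=True)
class DoubleExpKernel:
    """eta(s) = J_r exp(-s/tau_r) + J_a exp(-s/tau_a) for s >= tau_ref."""

    J_r: float
    tau_r: float
    J_a: float
    tau_a: float
    refractory: RefractorySpec = field(default_factory=RefractorySpec)

    def __post_init__(self) -> None:
        if not (self.tau_r > 0 and self.tau_a > 0):
            raise ValueError("time constants must be positive")

    def parametric(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (self.J_r * np.exp(-s / self.tau_r)
                + self.J_a * np.exp(-s / self.tau_a))

    @property
    def support_end(self) -> float:
        # each component below half the cutoff bounds the sum below the cutoff
        ends = [self.refractory.tau_ref]
        for J, tau in ((self.J_r, self.tau_r), (self.J_a, self.tau_a)):
            if J != 0.0:
                ends.append(tau * np.log(abs(J) / (0.5 * KERNEL_CUTOFF)))
        return max(ends)


@dataclass(frozen=True)
class BasisKernel:
    """eta(s) = sum_i beta_i B_i(s) on a raised-cosine basis."""

    beta: tuple
    basis: RaisedCosineBasis = field(default_factory=RaisedCosineBasis)
    refractory: RefractorySpec = field(default_factory=RefractorySpec)

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in np.atleast_1d(self.beta))
        object.__setattr__(self, "beta", beta)
        if len(beta) != self.basis.n:
            raise ValueError(
                f"beta has {len(beta)} entries, basis has {self.basis.n}")

    def parametric(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.basis.evaluate(np.ravel(s)) @ np.asarray(self.beta)

    @property
    def support_end(self) -> float:
        return max(self.refractory.tau_ref, self.basis.support_end)


HistoryKernel = Union[SingleExpKernel, DoubleExpKernel, BasisKernel]


@dataclass(frozen=True)
class Nonlinearity:
    """Mapping from log-drive to non-negative rate; phi(-inf) = 0 for all
    three variants."""

    tag: str

    _TAGS = ("exponential", "linear_rectifier", "softplus")

    def __post_init__(self) -> None:
        if self.tag not in self._TAGS:
            raise ValueError(f"unknown nonlinearity {self.tag!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.tag == "exponential":
            return np.exp(x)
        if self.tag == "linear_rectifier":
            return np.where(x > -1.0, x + 1.0, 0.0)
        # softplus: log(1 + e^x), numerically stable for large |x|
        return np.logaddexp(0.0, x)


EXPONENTIAL = Nonlinearity("exponential")
LINEAR_RECTIFIER = Nonlinearity("linear_rectifier")
SOFTPLUS = Nonlinearity("softplus")


@dataclass(frozen=True)
class HawkesModel:
    """Nonlinear Hawkes process: baseline I0, history kernel, nonlinearity."""

    I0: float
    kernel: HistoryKernel
    phi: Nonlinearity = EXPONENTIAL

    @property
    def c(self) -> float:
        """Baseline rate c = e^{I0} (s^-1)."""
        return float(np.exp(self.I0))

    @property
    def tau_ref(self) -> float:
        return self.kernel.refractory.tau_ref

    @property
    def lambda_max(self) -> float:
        """Rate ceiling imposed by the absolute refractory period
        (infinite when tau_ref = 0)."""
        if self.tau_ref == 0.0:
            return np.inf
        return 1.0 / self.tau_ref

    @property
    def lambda_thr(self) -> float:
        """Threshold above which a steady-state rate counts as
        unphysiological: 0.9 * lambda_max."""
        return 0.9 * self.lambda_max

    @classmethod
    def from_rate(cls, c: float, kernel: HistoryKernel,
                  phi: Nonlinearity = EXPONENTIAL) -> "HawkesModel":
        if not c > 0:
            raise ValueError("baseline rate c must be positive")
        return cls(I0=float(np.log(c)), kernel=kernel, phi=phi)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) on a trial of length ``duration``."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie in [0, duration]")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        return len(self) / self.duration

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def eval_kernel(kernel: HistoryKernel, s) -> np.ndarray:
    """Evaluate the spike-history kernel eta(s).

    Returns 0 for s < 0 (causality), -inf on [0, tau_ref) (absolute
    refractoriness), and the parametric/basis value for s >= tau_ref.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.zeros(s_arr.shape)
    tau_ref = kernel.refractory.tau_ref
    refr = (s_arr >= 0) & (s_arr < tau_ref)
    out[refr] = -np.inf
    rest = s_arr >= tau_ref
    if np.any(rest):
        out[rest] = kernel.parametric(s_arr[rest])
    if np.isscalar(s) or np.ndim(s) == 0:
        return out[0]
    return out


def _history_drive(kernel: HistoryKernel, times: np.ndarray, t: float) -> float:
    """Sum of eta(t - t_k) over history spikes within the kernel support."""
    if times.size == 0:
        return 0.0
    lags = t - times
    tau_ref = kernel.refractory.tau_ref
    if lags[-1] < tau_ref:
        return -np.inf
    keep = lags <= kernel.support_end
    if not np.any(keep):
        return 0.0
    return float(np.sum(kernel.parametric(lags[keep])))


def _check_history(times: np.ndarray, t: float) -> None:
    if times.size and times[-1] >= t:
        raise ValueError("all history spike times must be strictly before t")


def conditional_intensity(model: HawkesModel, history: SpikeTrain,
                          t: float) -> float:
    """Instantaneous firing rate lambda(t | H_t) = phi(I0 + sum eta(t-t_k)).

    Exactly zero within tau_ref of the most recent spike (phi(-inf) = 0).
    """
    _check_history(history.times, t)
    h = _history_drive(model.kernel, history.times, t)
    return float(model.phi(model.I0 + h))


def reset_conditional_intensity(model: HawkesModel, history: SpikeTrain,
                                t: float) -> float:
    """Renewal ("reset") variant: only the most recent spike contributes."""
    _check_history(history.times, t)
    if len(history) == 0:
        return float(model.phi(model.I0))
    last = history.times[-1:]
    h = _history_drive(model.kernel, last, t)
    return float(model.phi(model.I0 + h))


def intensity_on_grid(model: HawkesModel, train: SpikeTrain,
                      dt: float, n_bins: int | None = None) -> np.ndarray:
    """Conditional intensity at every bin start of a regular dt grid.

    Bin i covers [i*dt, (i+1)*dt); the intensity uses spikes strictly
    before the bin start (the convention shared by the simulator, the GLM
    likelihood and time-rescaling). Bins whose start falls within tau_ref
    of the previous spike have intensity exactly 0.
    """
    if n_bins is None:
        n_bins = int(np.round(train.duration / dt))
    times = train.times
    kern = model.kernel
    h = np.zeros(n_bins)
    support = kern.support_end
    for t_k in times:
        i0 = int(np.floor(t_k / dt)) + 1
        i1 = min(n_bins, int(np.floor((t_k + support) / dt)) + 1)
        if i0 >= n_bins:
            continue
        lags = np.arange(i0, i1) * dt - t_k
        h[i0:i1] += kern.parametric(lags)
    lam = np.asarray(model.phi(model.I0 + h), dtype=float)
    tau_ref = kern.refractory.tau_ref
    if tau_ref > 0 and times.size:
        starts = np.arange(n_bins) * dt
        idx = np.searchsorted(times, starts, side="left") - 1
        has_prev = idx >= 0
        lag_prev = np.where(has_prev, starts - times[np.clip(idx, 0, None)],
                            np.inf)
        # tiny slack so lags exactly at tau_ref survive float fuzz
        lam[lag_prev < tau_ref - 1e-12] = 0.0
    return lam
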