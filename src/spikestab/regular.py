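"""Regular-spiking escape analysis: divergence-rate lower bounds for fragile
models and the regular-spiking-limit / burst-duration conditions.

For a fragile model sitting at its low-rate fixed point A0, divergence can
occur through a run of K near-regular spikes with interval x. The
probability p_reg(x) of such a run following any spike is computed by
iterating the per-interval firing probabilities p(x, k) under a
quasi-renewal intensity that combines the regular spikes after t1 = 0 with
a Poisson-average (rate A0) pre-history. The divergence rate is then
bounded below by A0 * max_x p_reg(x), giving an upper bound on the expected
divergence time.

Independently of the quasi-renewal approximation, the condition

    sum_{k=1..K} eta(k x) >= -ln[ c (x - tau_ref) ]

states whether tonic firing at interval x can be sustained for K spikes
(K = inf: indefinitely); for exponential kernels the left-hand side is a
geometric series with a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .models import (BasisKernel, DoubleExpKernel, HawkesModel,
                     SingleExpKernel)
from .stability import _QRTables, _require_exponential

__all__ = [
    "RegularDivergenceResult",
    "RegularLimitResult",
    "p_regular_divergence",
    "predict_divergence_bound",
    "regular_limit_condition",
    "burst_duration",
    "geometric_lhs",
]

#: p(x, k) counts as "close to 1" above this value. The per-interval firing
#: probability saturates strictly below 1 once the kernel support is
#: exhausted (each further cycle keeps a constant escape chance), so the
#: threshold must sit below the saturation level of genuinely escaping
#: models; 0.99 admits the canonical fragile single-exponential examples
#: while purely refractory/inhibitory models still return 0.
P_CLOSE = 0.99
#: iteration cap on the number of regular intervals
K_CAP = 10_000
#: trapezoid sub-grid points per inter-spike segment
N_SUB = 50


@dataclass(frozen=True)
class RegularDivergenceResult:
    x_star: float          # maximizing regular interval (s)
    p_reg_max: float       # escape probability at x_star
    r_div_lower: float     # divergence-rate lower bound (s^-1)
    t_div_upper: float     # E[T_div] upper bound = 1 / r_div_lower (s)


@dataclass(frozen=True)
class RegularLimitResult:
    sustainable: bool           # tonic firing sustainable indefinitely
    x_min: Optional[float]      # smallest sustainable regular interval (s)
    k_max: float                # sustainable regular spikes at probe interval
    burst_duration: float       # k_max * x (s)
    probe_interval: float       # x used for k_max (s)


def _p_reg(tab: _QRTables, model: HawkesModel, a0: float, x: float) -> float:
    tau_ref = model.tau_ref
    # the intensity vanishes identically within tau_ref of the most recent
    # regular spike, so the quadrature grid covers [tau_ref, x] exactly
    u = np.linspace(min(tau_ref, x), x, N_SUB)
    eta0 = np.asarray(model.kernel.parametric(u), dtype=float)
    hist = np.zeros(N_SUB)  # sum over older regular spikes
    support = model.kernel.support_end
    p_prev = -1.0
    log_prod = 0.0
    for k in range(1, K_CAP + 1):
        expo = model.I0 + eta0 + hist + a0 * tab.G_at((k - 1) * x + u)
        lam = np.exp(np.minimum(expo, 700.0))
        integral = np.trapezoid(lam, u)
        p_k = -math.expm1(-integral)
        if p_k <= 0.0:
            return 0.0
        log_prod += math.log(p_k)
        if p_k > P_CLOSE:
            return math.exp(log_prod)
        if p_k <= p_prev:
            return 0.0
        p_prev = p_k
        if k * x <= support:
            hist = hist + np.asarray(model.kernel.parametric(u + k * x),
                                     dtype=float)
    return 0.0


def p_interval_sequence(model: HawkesModel, a0: float, x: float,
                        k_max: int) -> np.ndarray:
    """Diagnostic: the first ``k_max`` per-interval probabilities p(x, k).

    p(x, k) is the probability that the k-th regular interval of length x
    contains a spike, under the regular-spiking quasi-renewal intensity.
    """
    _require_exponential(model)
    tab = _QRTables(model)
    tau_ref = model.tau_ref
    u = np.linspace(min(tau_ref, x), x, N_SUB)
    eta0 = np.asarray(model.kernel.parametric(u), dtype=float)
    hist = np.zeros(N_SUB)
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        expo = model.I0 + eta0 + hist + a0 * tab.G_at((k - 1) * x + u)
        lam = np.exp(np.minimum(expo, 700.0))
        out[k - 1] = -math.expm1(-np.trapezoid(lam, u))
        if k * x <= model.kernel.support_end:
            hist = hist + np.asarray(model.kernel.parametric(u + k * x),
                                     dtype=float)
    return out


def p_regular_divergence(model: HawkesModel, a0: float, x: float) -> float:
    """Probability p_reg(x) that a spike triggers a divergent regular run.

    Iterates p(x, k) while it increases monotonically towards 1; returns
    the product of the terms once p(x, k) exceeds 1 - 1e-6, and 0 as soon
    as the monotone increase breaks (the interval x does not lead to
    regular divergence).
    """
    _require_exponential(model)
    if not (model.tau_ref <= x <= 1.0 / a0 + 1e-12):
        raise ValueError("require tau_ref <= x <= 1/a0")
    tab = _QRTables(model)
    return _p_reg(tab, model, a0, x)


def predict_divergence_bound(model: HawkesModel, a0: float,
                             n_x: int = 200) -> RegularDivergenceResult:
    """Maximize p_reg over x in [tau_ref, 1/a0]; bound the divergence rate.

    r_div >= A0 * max_x p_reg(x), hence E[T_div] <= 1 / (A0 max_x p_reg).
    """
    _require_exponential(model)
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    tab = _QRTables(model)
    hi = max(1.0 / a0, model.tau_ref * 1.01)
    # log-dense near tau_ref: the escape window x - tau_ref spans orders of
    # magnitude and p_reg is typically maximal just above tau_ref
    xs = model.tau_ref + np.geomspace(1e-6, hi - model.tau_ref, n_x)
    ps = np.array([_p_reg(tab, model, a0, x) for x in xs])
    i = int(np.argmax(ps))
    p_max = float(ps[i])
    r_low = a0 * p_max
    t_up = np.inf if r_low == 0.0 else 1.0 / r_low
    return RegularDivergenceResult(x_star=float(xs[i]), p_reg_max=p_max,
                                   r_div_lower=r_low, t_div_upper=t_up)


def geometric_lhs(J: float, tau: float, x: float, K: Union[int, float]) -> float:
    """Closed form of sum_{k=1..K} J exp(-k x / tau) (geometric series)."""
    if np.isinf(K):
        return J / math.expm1(x / tau)
    q = math.exp(-x / tau)
    return J * q * (1.0 - q ** K) / (1.0 - q)


def _eta_partial_sum(model: HawkesModel, x: float,
                     K: Union[int, float]) -> float:
    """sum_{k=1..K} eta(k x), exact closed form for exponential kernels."""
    kern = model.kernel
    if isinstance(kern, SingleExpKernel):
        return geometric_lhs(kern.J, kern.tau, x, K)
    if isinstance(kern, DoubleExpKernel):
        return (geometric_lhs(kern.J_r, kern.tau_r, x, K)
                + geometric_lhs(kern.J_a, kern.tau_a, x, K))
    # basis kernels: direct summation to the kernel support cutoff (the
    # contribution beyond is below the numerical cutoff by construction)
    k_hi = int(np.ceil(kern.support_end / x))
    if not np.isinf(K):
        k_hi = min(k_hi, int(K))
    if k_hi < 1:
        return 0.0
    ks = np.arange(1, k_hi + 1)
    return float(np.sum(kern.parametric(ks * x)))


def regular_limit_condition(model: HawkesModel, x: float,
                            K: Union[int, float] = np.inf) -> bool:
    """Whether tonic firing at interval x is sustainable for K spikes.

    Evaluates sum_{k=1..K} eta(k x) >= -ln[c (x - tau_ref)].
    """
    if x <= model.tau_ref:
        raise ValueError("x must exceed tau_ref")
    rhs = -math.log(model.c * (x - model.tau_ref))
    return bool(_eta_partial_sum(model, x, K) >= rhs)


def burst_duration(model: HawkesModel,
                   probe_rate_fraction: float = 0.9,
                   x_min_scan: int = 500) -> RegularLimitResult:
    """Burst-length analysis at a probe interval near the refractory period.

    The probe interval satisfies 1/x = probe_rate_fraction / tau_ref.
    k_max is the largest K for which tonic firing at interval x can be
    sustained (infinite when the K = inf condition holds); burst_duration
    = k_max * x approximates the length of intermittent regular-spiking
    episodes. x_min is the smallest interval sustainable indefinitely
    (None if no interval on the scanned range is).
    """
    if not 0 < probe_rate_fraction < 1:
        raise ValueError("probe_rate_fraction must be in (0, 1)")
    if model.tau_ref == 0:
        raise ValueError("burst analysis requires tau_ref > 0")
    x = model.tau_ref / probe_rate_fraction
    sustainable = regular_limit_condition(model, x, np.inf)
    if sustainable:
        k_max: float = np.inf
        dur: float = np.inf
    else:
        # partial sums are constant once k x exceeds the kernel support, so
        # the largest satisfying K is bounded by support / x
        cap = min(1_000_000, int(np.ceil(model.kernel.support_end / x)) + 1)
        ks = np.arange(1, cap + 1)
        partial = np.cumsum(np.asarray(model.kernel.parametric(ks * x),
                                       dtype=float))
        rhs = -math.log(model.c * (x - model.tau_ref))
        ok = np.nonzero(partial >= rhs)[0]
        k_max = float(ok[-1] + 1) if ok.size else 0.0
        dur = k_max * x
    # smallest indefinitely-sustainable interval
    x_hi = max(1.0, model.tau_ref + 10.0 / model.c)
    xs = np.geomspace(model.tau_ref * 1.0001 + 1e-12, x_hi, x_min_scan)
    x_min = None
    for xi in xs:
        if regular_limit_condition(model, xi, np.inf):
            x_min = float(xi)
            break
    return RegularLimitResult(sustainable=sustainable, x_min=x_min,
                              k_max=k_max, burst_duration=dur,
                              probe_interval=x)
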