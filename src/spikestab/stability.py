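"""Quasi-renewal (QR) stability analysis of nonlinear Hawkes models.

The QR approximation replaces the spike history before the most recent spike
by a homogeneous Poisson history of rate A0, giving the tractable intensity

    lambda0(tau) = c * exp(eta(tau)) * exp(A0 * G(tau)),
    G(tau) = int_tau^inf gamma(u) du,   gamma(u) = exp(eta(u)) - 1,

from which the survivor function S0, the inter-spike-interval density P0 and
the transfer function f(A0) = [int_0^inf S0(tau) dtau]^(-1) follow as for an
ordinary renewal process. Fixed points f(A0) = A0 are the candidate
steady-state rates; the model is classified stable / fragile / divergent by
where its stable fixed points lie relative to lambda_thr = 0.9 / tau_ref.

The derivation relies on the moment-generating functional of the Poisson
history and is specific to the exponential nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional

import numpy as np

from .basis import RaisedCosineBasis
from .models import BasisKernel, HawkesModel

__all__ = [
    "QRCurves",
    "TransferCurve",
    "FixedPoint",
    "StabilityReport",
    "UnsupportedModelError",
    "qr_intensity",
    "transfer_function",
    "find_fixed_points",
    "classify",
]

#: default lag-grid spacing (s); resolves the refractory edge
DT_QR = 1e-4
#: default number of A0 samples when scanning for fixed points
N_GRID = 400
#: root tolerance, in units of lambda_max
ROOT_TOL = 1e-6
#: centered-difference step and root-merge tolerance, in units of lambda_max
DERIV_STEP = 1e-3


class UnsupportedModelError(ValueError):
    """Raised when the QR machinery is asked for a non-exponential model."""


@dataclass(frozen=True)
class QRCurves:
    """QR intensity, survivor, ISI density and gamma-tail on a lag grid."""

    tau_grid: np.ndarray
    lambda0: np.ndarray
    survivor: np.ndarray
    isi_density: np.ndarray
    gamma_tail: np.ndarray  # G(tau) = int_tau^inf gamma(u) du

    @property
    def Gamma_total(self) -> float:
        """Gamma = int_0^inf gamma(u) du = G(0)."""
        return float(self.gamma_tail[0])


@dataclass(frozen=True)
class TransferCurve:
    a0_grid: np.ndarray
    f_values: np.ndarray


@dataclass(frozen=True)
class FixedPoint:
    a0_hat: float
    stable: bool
    degenerate: bool = False  # merged near-tangent roots


@dataclass(frozen=True)
class StabilityReport:
    label: str  # stable | fragile | divergent
    fixed_points: List[FixedPoint]
    lambda_thr: float
    predicted_rate: Optional[float]  # lowest stable fixed point (s^-1)
    t_div_bound: Optional[float]  # upper bound on E[T_div] (s), fragile only


@lru_cache(maxsize=8)
def _basis_matrix(basis: RaisedCosineBasis, tau_ref: float, dt: float,
                  n: int) -> np.ndarray:
    tau = tau_ref + np.arange(n) * dt
    return basis.evaluate(tau)


class _QRTables:
    """Per-model lag-grid tables; the A0 dependence is then a cheap rescale.

    eta, exp(eta) and G are evaluated once on a uniform grid covering
    [tau_ref, s_max] (s_max = kernel support cutoff). Beyond s_max the
    kernel is numerically zero, so lambda0 = c exactly and integrals over
    the tail are closed-form.
    """

    def __init__(self, model: HawkesModel, dt: float = DT_QR):
        _require_exponential(model)
        self.model = model
        self.dt = dt
        tau_ref = model.tau_ref
        s_max = max(model.kernel.support_end, tau_ref) + dt
        # grid over [tau_ref, s_max]; lambda0 = 0 identically below tau_ref
        n = int(np.ceil((s_max - tau_ref) / dt)) + 1
        self.tau = tau_ref + np.arange(n) * dt
        kern = model.kernel
        if isinstance(kern, BasisKernel):
            # the basis matrix on the lag grid is parameter-independent;
            # cache it so repeated classifications (e.g. inside the
            # stabilized fit) only pay a matrix-vector product
            B = _basis_matrix(kern.basis, float(tau_ref), float(dt), n)
            self.eta = B @ np.asarray(kern.beta)
        else:
            self.eta = np.asarray(kern.parametric(self.tau), dtype=float)
        self.exp_eta = np.exp(self.eta)
        gamma = self.exp_eta - 1.0
        # G on the grid: integrate gamma from the top (G(s_max) ~ 0)
        incr = 0.5 * (gamma[1:] + gamma[:-1]) * np.diff(self.tau)
        G = np.concatenate([np.cumsum(incr[::-1])[::-1], [0.0]])
        self.G = G
        # refractory segment contributes gamma = -1 exactly on [0, tau_ref)
        self.G0 = G[0] - tau_ref  # = G(0)

    def lambda0(self, a0: float) -> np.ndarray:
        """lambda0(tau) on the grid (tau >= tau_ref)."""
        with np.errstate(over="ignore"):  # inf intensity -> S0 drops to 0
            return self.model.c * self.exp_eta * np.exp(a0 * self.G)

    def transfer(self, a0: float, chunk: int = 4096) -> float:
        """f(A0) = [int_0^inf S0]^-1 with the exact exponential tail.

        Integration proceeds in blocks and stops once S0 < 1e-13 (the
        remaining mass is below ~1e-12 of the area); if the whole grid is
        consumed, the constant-rate tail beyond the kernel support
        contributes S0(end)/c exactly.
        """
        c = self.model.c
        n = self.tau.size
        area = self.model.tau_ref  # S0 = 1 on [0, tau_ref]
        cum = 0.0
        S_last = 1.0
        lam_last = 0.0
        i0 = 0
        truncated = False
        with np.errstate(over="ignore"):
            while i0 < n:
                i1 = min(i0 + chunk, n)
                lam = c * self.exp_eta[i0:i1] * np.exp(a0 * self.G[i0:i1])
                if i0 == 0:
                    seg_lam = lam
                    seg_tau = self.tau[i0:i1]
                else:
                    seg_lam = np.concatenate([[lam_last], lam])
                    seg_tau = self.tau[i0 - 1:i1]
                incr = 0.5 * (seg_lam[1:] + seg_lam[:-1]) * np.diff(seg_tau)
                cums = cum + np.cumsum(incr)
                S = np.exp(-cums)
                S_full = np.concatenate([[S_last], S])
                area += np.trapezoid(S_full, seg_tau)
                cum = cums[-1] if cums.size else cum
                S_last = S[-1] if S.size else S_last
                lam_last = lam[-1]
                if cum > 30.0 and i1 < n:
                    truncated = True
                    break
                i0 = i1
        if not truncated:
            # beyond s_max: lambda0 = c exactly -> tail integral S0(end)/c
            area += S_last / c
        return 1.0 / area

    def G_at(self, t) -> np.ndarray:
        """Interpolated G(t) for arbitrary t >= 0 (0 beyond the support)."""
        t = np.asarray(t, dtype=float)
        below = t < self.model.tau_ref
        out = np.interp(t, self.tau, self.G, left=self.G[0], right=0.0)
        # linear-in-t refractory segment: G(t) = G(tau_ref) + (tau_ref - t)*(-1)
        out = np.where(below, self.G[0] - (self.model.tau_ref - t), out)
        return out


def _require_exponential(model: HawkesModel) -> None:
    if model.phi.tag != "exponential":
        raise UnsupportedModelError(
            "the quasi-renewal transfer function is derived for the "
            "exponential nonlinearity only")


def qr_intensity(model: HawkesModel, a0: float, dt: float = DT_QR) -> QRCurves:
    """QR conditional intensity and derived renewal curves at rate a0."""
    if a0 < 0:
        raise ValueError("a0 must be non-negative")
    tab = _QRTables(model, dt)
    # prepend the refractory segment so curves start at tau = 0
    n_ref = int(np.round(model.tau_ref / dt))
    tau_ref_grid = np.arange(n_ref) * dt
    tau = np.concatenate([tau_ref_grid, tab.tau])
    lam_param = tab.lambda0(a0)
    lam = np.concatenate([np.zeros(n_ref), lam_param])
    incr = 0.5 * (lam_param[1:] + lam_param[:-1]) * np.diff(tab.tau)
    cum = np.concatenate([np.zeros(n_ref + 1), np.cumsum(incr)])
    S0 = np.exp(-cum)
    G = tab.G_at(tau)
    return QRCurves(tau_grid=tau, lambda0=lam, survivor=S0,
                    isi_density=S0 * lam, gamma_tail=G)


def transfer_function(model: HawkesModel, a0, dt: float = DT_QR):
    """Predicted steady-state rate f(A0) for one or many assumed rates."""
    tab = _QRTables(model, dt)
    if np.ndim(a0) == 0:
        if a0 < 0:
            raise ValueError("a0 must be non-negative")
        return tab.transfer(float(a0))
    return np.array([tab.transfer(float(a)) for a in np.asarray(a0)])


def transfer_curve(model: HawkesModel, n_grid: int = N_GRID,
                   dt: float = DT_QR) -> TransferCurve:
    """Sample f(A0) on the fixed-point scan grid over [0, lambda_max]."""
    tab = _QRTables(model, dt)
    grid = _a0_grid(model.lambda_max, n_grid)
    f = np.array([tab.transfer(a) for a in grid])
    return TransferCurve(a0_grid=grid, f_values=f)


def _a0_grid(lam_max: float, n_grid: int) -> np.ndarray:
    """Grid on [0, lambda_max], log-dense near both ends."""
    n_half = max(n_grid // 2, 4)
    lo = np.geomspace(lam_max * 1e-5, lam_max / 2, n_half)
    hi = lam_max - np.geomspace(lam_max * 1e-5, lam_max / 2, n_half)
    return np.unique(np.concatenate([[0.0], lo, hi[::-1], [lam_max]]))


def find_fixed_points(model: HawkesModel, n_grid: int = N_GRID,
                      dt: float = DT_QR) -> List[FixedPoint]:
    """Roots of g(A0) = f(A0) - A0, with local stability from sign(g').

    Sign changes of g on the scan grid are bracketed and refined by
    bisection to |g| < 1e-6 * lambda_max; stability uses a centered finite
    difference of g. Roots closer than 1e-3 * lambda_max are merged and
    flagged as degenerate (near-tangency).
    """
    if not model.tau_ref > 0:
        raise UnsupportedModelError(
            "fixed-point classification requires tau_ref > 0 (without an "
            "absolute refractory period a stable fixed point is not "
            "guaranteed)")
    tab = _QRTables(model, dt)
    lam_max = model.lambda_max

    def g(a0: float) -> float:
        return tab.transfer(a0) - a0

    grid = _a0_grid(lam_max, n_grid)
    gv = np.array([g(a) for a in grid])
    roots: List[float] = []
    tol = ROOT_TOL * lam_max
    for i in range(len(grid) - 1):
        if gv[i] == 0.0:
            roots.append(grid[i])
            continue
        if np.sign(gv[i]) * np.sign(gv[i + 1]) < 0:
            lo_, hi_ = grid[i], grid[i + 1]
            glo = gv[i]
            for _ in range(200):
                mid = 0.5 * (lo_ + hi_)
                gm = g(mid)
                if abs(gm) < tol and (hi_ - lo_) < tol:
                    break
                if np.sign(gm) == np.sign(glo):
                    lo_, glo = mid, gm
                else:
                    hi_ = mid
            roots.append(0.5 * (lo_ + hi_))
    if gv[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise RuntimeError(
            "no sign change of f(A0) - A0 bracketed; increase n_grid")
    # merge near-tangent roots
    roots = sorted(roots)
    merged: List[List[float]] = [[roots[0]]]
    for r in roots[1:]:
        if r - merged[-1][-1] < DERIV_STEP * lam_max:
            merged[-1].append(r)
        else:
            merged.append([r])
    out: List[FixedPoint] = []
    h = DERIV_STEP * lam_max
    for group in merged:
        r = float(np.mean(group))
        lo_p, hi_p = max(r - h, 0.0), min(r + h, lam_max)
        gp = (g(hi_p) - g(lo_p)) / (hi_p - lo_p)
        out.append(FixedPoint(a0_hat=r, stable=bool(gp < 0),
                              degenerate=len(group) > 1))
    return out


def classify(model: HawkesModel, n_grid: int = N_GRID,
             dt: float = DT_QR,
             t_div_bound: bool = True) -> StabilityReport:
    """Classify the model as stable / fragile / divergent.

    Stable fixed points all below lambda_thr -> stable; all at or above ->
    divergent; on both sides -> fragile (metastable), in which case an
    upper bound on the expected divergence time is attached (computed from
    the regular-spiking escape analysis at the low-rate fixed point).
    A stable fixed point exactly at lambda_thr counts as divergent-side.
    """
    fps = find_fixed_points(model, n_grid=n_grid, dt=dt)
    stable_fps = [fp for fp in fps if fp.stable]
    if not stable_fps:
        raise RuntimeError("no stable fixed point found; with tau_ref > 0 "
                           "at least one must exist")
    thr = model.lambda_thr
    below = [fp for fp in stable_fps if fp.a0_hat < thr]
    above = [fp for fp in stable_fps if fp.a0_hat >= thr]
    if not above:
        label = "stable"
    elif not below:
        label = "divergent"
    else:
        label = "fragile"
    predicted = min((fp.a0_hat for fp in stable_fps), default=None)
    bound = None
    if label == "fragile" and t_div_bound:
        from .regular import predict_divergence_bound
        low = min(fp.a0_hat for fp in below)
        bound = predict_divergence_bound(model, low).t_div_upper
    return StabilityReport(label=label, fixed_points=fps, lambda_thr=thr,
                           predicted_rate=predicted, t_div_bound=bound)
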