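"""Raised-cosine basis for spike-history filters.

The basis follows the standard log-time raised-cosine construction used for
post-spike filters in point-process GLMs: each function is half a cosine bump
in warped time ``f(t) = log(t + psi)``, with peaks equally spaced in warped
time (i.e. logarithmically spaced in real time) and a width of two peak
spacings on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RaisedCosineBasis"]


@dataclass(frozen=True)
class RaisedCosineBasis:
    """Log-spaced raised-cosine basis functions B_i(s).

    Parameters
    ----------
    n : int
        Number of basis functions (default 10).
    peak_first, peak_last : float
        Locations (s) of the first and last peak. Peaks are equally spaced
        in ``log(t + psi)`` between these two.
    psi : float
        Log-warping offset (s); sets how strongly early lags are stretched.
    """

    n: int = 10
    peak_first: float = 0.002
    peak_last: float = 0.4
    psi: float = 0.002

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 basis functions")
        if not 0 < self.peak_first < self.peak_last:
            raise ValueError("require 0 < peak_first < peak_last")
        if self.psi <= 0:
            raise ValueError("psi must be positive")

    def _warp(self, t: np.ndarray) -> np.ndarray:
        return np.log(t + self.psi)

    @property
    def _centers(self) -> np.ndarray:
        return np.linspace(
            np.log(self.peak_first + self.psi),
            np.log(self.peak_last + self.psi),
            self.n,
        )

    @property
    def _spacing(self) -> float:
        c = self._centers
        return float(c[1] - c[0])

    @property
    def support_end(self) -> float:
        """Lag (s) beyond which every basis function is exactly zero."""
        return float(np.exp(self._centers[-1] + 2.0 * self._spacing) - self.psi)

    def peaks(self) -> np.ndarray:
        return np.exp(self._centers) - self.psi

    def evaluate(self, s) -> np.ndarray:
        """Evaluate all basis functions at lags ``s``.

        Returns an array of shape ``(len(s), n)``; rows for s < 0 are zero
        (causality).
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.zeros((s.size, self.n))
        ok = s >= 0.0
        if np.any(ok):
            w = self._warp(s[ok])[:, None]
            arg = (w - self._centers[None, :]) * (np.pi / (2.0 * self._spacing))
            vals = 0.5 * (1.0 + np.cos(np.clip(arg, -np.pi, np.pi)))
            vals[np.abs(arg) >= np.pi] = 0.0
            out[ok] = vals
        return out
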