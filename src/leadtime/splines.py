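"""Restricted cubic splines on the log-time scale.

The basis is the classical Durrleman–Simon / Royston–Parmar construction:
piecewise cubic, twice continuously differentiable, and constrained to be
linear beyond the boundary knots.  With K knots the basis has K - 1 columns
(``df = K - 1``); the first column is the identity, so a 2-knot spline is a
straight line and the survival model built on it reduces to a Weibull.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RestrictedCubicSpline", "event_centile_knots"]


def _cube_pos(u: np.ndarray) -> np.ndarray:
    """Truncated cube (u)_+^3."""
    return np.where(u > 0.0, u, 0.0) ** 3


def _square_pos(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 2


class RestrictedCubicSpline:
    """Restricted cubic spline basis with fixed knots.

    Parameters
    ----------
    knots:
        Strictly increasing knot locations (boundary knots included).
        At least two knots are required.
    """

    def __init__(self, knots) -> None:
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("at least two knots are required")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots

    @property
    def df(self) -> int:
        """Degrees of freedom: number of knots minus one."""
        return self.knots.size - 1

    def basis(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; returns shape ``x.shape + (df,)``."""
        x = np.asarray(x, dtype=float)
        k = self.knots
        kmin, kmax = k[0], k[-1]
        out = np.empty(x.shape + (self.df,), dtype=float)
        out[..., 0] = x
        for j in range(1, self.df):
            lam = (kmax - k[j]) / (kmax - kmin)
            out[..., j] = (
                _cube_pos(x - k[j])
                - lam * _cube_pos(x - kmin)
                - (1.0 - lam) * _cube_pos(x - kmax)
            )
        return out

    def derivative(self, x) -> np.ndarray:
        """First derivative of each basis column at ``x``."""
        x = np.asarray(x, dtype=float)
        k = self.knots
        kmin, kmax = k[0], k[-1]
        out = np.empty(x.shape + (self.df,), dtype=float)
        out[..., 0] = 1.0
        for j in range(1, self.df):
            lam = (kmax - k[j]) / (kmax - kmin)
            out[..., j] = 3.0 * (
                _square_pos(x - k[j])
                - lam * _square_pos(x - kmin)
                - (1.0 - lam) * _square_pos(x - kmax)
            )
        return out


def event_centile_knots(log_event_times, df: int) -> np.ndarray:
    """Default knot placement: boundaries at the min/max of the log event
    times, internal knots at equally spaced centiles (33/67 for ``df=3``).
    """
    t = np.asarray(log_event_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two event times to place knots")
    if df < 1:
        raise ValueError("df must be >= 1")
    centiles = np.linspace(0.0, 100.0, df + 1)
    knots = np.percentile(t, centiles)
    knots = np.unique(knots)
    if knots.size != df + 1:
        raise ValueError("degenerate event-time distribution: tied knots")
    return knots
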