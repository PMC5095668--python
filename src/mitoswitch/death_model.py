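"""Deterministic single-cell death times in the infinite-pore limit.

For a very large pore (A -> infinity) the CytC switch becomes a hard
threshold on free Bak monomer: a cell dies at the moment its total
anti-apoptotic inhibition, expressed in units of Bak,

    I(t) = m0 * exp(-t / tau_M) + x0 * exp(-t / tau_X)

decays through the dimensionless threshold theta ~ B_T / K_c.  Here m0 and
x0 are the initial Mcl-1/Bak and Bcl-xL/Bak ratios (each scaled by the
corresponding dissociation constant, which never needs to be known
separately), and tau_M, tau_X are the protein decay time constants during
mitotic arrest.  Cells already at or below threshold die at t = 0; optional
additive decay floors (m_s, x_s) can keep I(t) above theta forever, in which
case the death time is infinite.

All operations accept scalars or numpy arrays (broadcast together), since
population-level callers evaluate whole cohorts at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["CellState", "inhibition", "death_time"]


@dataclass(frozen=True)
class CellState:
    """Dimensionless protein state of one cell (or arrays of cells)."""

    m0: float | np.ndarray
    x0: float | np.ndarray
    tau_M: float | np.ndarray
    tau_X: float | np.ndarray
    theta: float | np.ndarray
    m_s: float | np.ndarray = 0.0
    x_s: float | np.ndarray = 0.0

    def __post_init__(self):
        m0, x0, tau_M, tau_X, theta = map(
            np.asarray, (self.m0, self.x0, self.tau_M, self.tau_X, self.theta)
        )
        if np.any(m0 < 0) or np.any(x0 < 0):
            raise ValidationError("m0 and x0 must be >= 0")
        if np.any(tau_M <= 0) or np.any(tau_X <= 0):
            raise ValidationError("decay time constants must be positive")
        if np.any(theta <= 0):
            raise ValidationError("death threshold theta must be positive")


def inhibition(t, c: CellState):
    """Total Bak inhibition I(t); strictly decreasing when m0 + x0 > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    out = (
        c.m_s + (np.asarray(c.m0) - c.m_s) * np.exp(-t / np.asarray(c.tau_M))
        + c.x_s + (np.asarray(c.x0) - c.x_s) * np.exp(-t / np.asarray(c.tau_X))
    )
    return float(out) if out.ndim == 0 else out


def death_time(c: CellState, rel_tol: float = 1e-12):
    """Time t_c at which I(t_c) = theta.

    Returns 0 where I(0) <= theta, +inf where the decay floors keep I above
    theta forever, and otherwise the unique root of the monotone decay,
    located by vectorized bisection to relative tolerance ``rel_tol`` of the
    bracket (unit-agnostic; the single-exponential case x0 = 0,
    m_s = x_s = 0 uses its closed form).
    """
    m0, x0, tau_M, tau_X, theta, m_s, x_s = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in
          (c.m0, c.x0, c.tau_M, c.tau_X, c.theta, c.m_s, c.x_s))
    )
    scalar = m0.ndim == 0
    m0, x0, tau_M, tau_X, theta, m_s, x_s = (
        np.atleast_1d(v) for v in (m0, x0, tau_M, tau_X, theta, m_s, x_s)
    )

    out = np.zeros(m0.shape)
    i0 = m0 + x0 <= theta                      # dead (or safe) at onset: t_c = 0
    never = (m_s + x_s >= theta) & ~i0         # floors hold I above theta
    out[never] = np.inf
    pending = ~i0 & ~never

    # closed form for the pure-Mcl-1 exponential
    pure = pending & (x0 == 0) & (m_s == 0) & (x_s == 0)
    if pure.any():
        out[pure] = tau_M[pure] * np.log(m0[pure] / theta[pure])
        pending &= ~pure

    if pending.any():
        idx = np.flatnonzero(pending)
        mm0, xx0, tm, tx, th = (a[idx] for a in (m0, x0, tau_M, tau_X, theta))
        ms, xs = m_s[idx], x_s[idx]

        def I(t):
            return (ms + (mm0 - ms) * np.exp(-t / tm)
                    + xs + (xx0 - xs) * np.exp(-t / tx))

        hi = 10.0 * np.maximum(tm, tx)
        # extend the bracket where needed (I is monotone decreasing)
        for _ in range(64):
            bad = I(hi) > th
            if not bad.any():
                break
            hi = np.where(bad, 2.0 * hi, hi)
        lo = np.zeros_like(hi)
        # enough halvings to resolve rel_tol even after bracket doubling
        n_iter = int(np.ceil(-np.log2(rel_tol))) + 65
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            above = I(mid) > th
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
        out[idx] = 0.5 * (lo + hi)

    return float(out[0]) if scalar else out
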