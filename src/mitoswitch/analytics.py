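"""Closed-form quasi-static solutions of the Bak pore switch.

When Mcl-1 degradation is slow compared to Bak binding, oligomerization and
CytC translocation, every fast species sits at equilibrium conditional on the
instantaneous free Mcl-1 level M(t), which itself obeys

    dM/dt = sigma_M - delta_M * M
    M(t)  = M_s + (M_0 - M_s) exp(-delta_M t),   M_s = sigma_M / delta_M.

Bak monomer then follows B_1 = B_T / (1 + M/K_M), and the cytoplasmic CytC
fraction is a Hill function of B_1 with exponent equal to the pore subunit
count A:

    f = B_1^A / (B_1^A + K_C^A)

where K_C is the monomer level at half-maximal release.  From these, the
MOMP delay T_c and the 1/10 -> 1/2 switch duration Delta_T follow in closed
form, with the pore-size lower bound Delta_T >= ln(9) / (A * delta_M).

The closed forms retain the synthesis floor M_s; setting sigma_M = 0
recovers the floorless expressions exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .kinetics import KineticModel, KineticParameters

__all__ = [
    "QuasiStaticParams",
    "free_mcl1",
    "bak_monomer",
    "cytc_fraction",
    "critical_bak",
    "critical_mcl1",
    "momp_delay",
    "switch_sharpness",
    "switch_bound",
    "calibrate_kc",
    "quasistatic_from_kinetics",
    "NEVER_FIRES",
]

#: Constant in the switch-sharpness bound: Delta_T >= ln(9)/(A * delta_M).
SHARPNESS_CONSTANT = math.log(9.0)

#: Sentinel returned by momp_delay when the threshold is below the synthesis
#: floor, so the switch never fires.
NEVER_FIRES = math.inf


@dataclass(frozen=True)
class QuasiStaticParams:
    """Parameters of the reduced one-variable model (nM, seconds)."""

    M_0: float        # initial free Mcl-1
    M_s: float        # steady-state free Mcl-1 = sigma_M / delta_M
    delta_M: float    # Mcl-1 degradation rate
    B_T: float        # total Bak
    K_M: float        # Mcl-1:Bak dissociation constant
    A: int            # pore subunit count
    K_C: float        # Bak monomer level at half-maximal CytC release

    def __post_init__(self):
        if not (self.M_0 > self.M_s >= 0):
            raise ValidationError("require M_0 > M_s >= 0")
        if self.K_M <= 0 or self.K_C <= 0 or self.B_T <= 0 or self.delta_M <= 0:
            raise ValidationError("K_M, K_C, B_T, delta_M must be positive")
        if self.A < 2:
            raise ValidationError("pore size A must be >= 2")


def free_mcl1(t, p: QuasiStaticParams):
    """Free Mcl-1 level M(t) = M_s + (M_0 - M_s) exp(-delta_M t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    out = p.M_s + (p.M_0 - p.M_s) * np.exp(-p.delta_M * t)
    return float(out) if out.ndim == 0 else out


def bak_monomer(M_free, p: QuasiStaticParams):
    """Free Bak monomer at binding equilibrium: B_1 = B_T / (1 + M/K_M)."""
    M_free = np.asarray(M_free, dtype=float)
    if np.any(M_free < 0):
        raise ValidationError("M_free must be >= 0")
    out = p.B_T / (1.0 + M_free / p.K_M)
    return float(out) if out.ndim == 0 else out


def cytc_fraction(B_1, p: QuasiStaticParams):
    """Cytoplasmic CytC fraction f = B_1^A / (B_1^A + K_C^A).

    Evaluated in log space so that A = 256 does not overflow.
    """
    B_1 = np.asarray(B_1, dtype=float)
    if np.any(B_1 < 0):
        raise ValidationError("B_1 must be >= 0")
    with np.errstate(divide="ignore"):
        # f = 1 / (1 + exp(A * (ln K_C - ln B_1)))  -- a logistic in log B_1
        z = p.A * (np.log(p.K_C) - np.log(B_1))
    out = np.where(np.isposinf(z), 0.0, 1.0 / (1.0 + np.exp(np.minimum(z, 700.0))))
    return float(out) if out.ndim == 0 else out


def critical_bak(p: QuasiStaticParams, fraction: float = 0.5) -> float:
    """Bak monomer level at which the CytC fraction equals ``fraction``:
    B_1(f) = K_C * (f/(1-f))^(1/A)."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    return p.K_C * (fraction / (1.0 - fraction)) ** (1.0 / p.A)


def critical_mcl1(p: QuasiStaticParams, fraction: float = 0.5) -> float:
    """Free Mcl-1 level at which the CytC fraction equals ``fraction``.

    Inverts cytc_fraction o bak_monomer analytically:
    B_1(f) = K_C * (f/(1-f))^(1/A), then M = K_M * (B_T/B_1 - 1).
    Returns 0 when even fully de-repressed Bak (B_1 = B_T) cannot reach
    ``fraction``.
    """
    b1 = critical_bak(p, fraction)
    if b1 >= p.B_T:
        return 0.0
    return p.K_M * (p.B_T / b1 - 1.0)


def momp_delay(p: QuasiStaticParams) -> float:
    """Delay T_c (s) until half-maximal CytC release.

    T_c = (1/delta_M) * ln((M_0 - M_s)/(M_1/2 - M_s)); returns 0 when the
    threshold M_1/2 already exceeds M_0, and ``NEVER_FIRES`` (inf) when the
    synthesis floor keeps free Mcl-1 above the threshold forever.
    """
    m_half = critical_mcl1(p, 0.5)
    if m_half >= p.M_0:
        return 0.0
    if m_half <= p.M_s:
        return NEVER_FIRES
    return math.log((p.M_0 - p.M_s) / (m_half - p.M_s)) / p.delta_M


def switch_sharpness(p: QuasiStaticParams) -> float:
    """Exact reduced-model switch duration Delta_T = t(1/2) - t(1/10) (s).

    Equals the pore-size bound ln(9)/(A delta_M) exactly in the regime
    M >> K_M (Bak mostly sequestered); exceeds it otherwise.
    """
    m_half = critical_mcl1(p, 0.5)
    m_tenth = critical_mcl1(p, 0.1)
    if m_half <= p.M_s or m_tenth <= p.M_s:
        return NEVER_FIRES
    t_half = momp_delay(p)
    t_tenth = (
        0.0 if m_tenth >= p.M_0
        else math.log((p.M_0 - p.M_s) / (m_tenth - p.M_s)) / p.delta_M
    )
    return t_half - t_tenth


def switch_bound(A: int, delta_M: float) -> float:
    """Pore-size lower bound on the switch duration: ln(9)/(A*delta_M) (s)."""
    if A < 2:
        raise ValidationError("pore size A must be >= 2")
    if delta_M <= 0:
        raise ValidationError("delta_M must be positive")
    return SHARPNESS_CONSTANT / (A * delta_M)


# ---------------------------------------------------------------------------
# Calibration of K_C against the full network
# ---------------------------------------------------------------------------

def _steady_log_pore(log_b1: float, model: KineticModel) -> float:
    """log concentration of the pore species at ladder equilibrium, given
    a clamped monomer level exp(log_b1)."""
    log_b = log_b1
    for k in range(model.n_steps):
        log_k = math.log(model.betas[k]) - math.log(model.alphas[k])
        log_b = 2.0 * log_b - log_k
    return log_b


def calibrate_kc(model: KineticModel) -> float:
    """Bak monomer level K_C (nM) giving half-maximal steady CytC release.

    Clamps the monomer concentration, propagates the dimerization ladder at
    equilibrium, and locates by root finding the monomer level where the
    steady-state CytC fraction gamma_m*B_A/(gamma_m*B_A + gamma_c) is 1/2,
    i.e. where B_A = gamma_c/gamma_m.  Works in log space so the A = 256
    ladder stays well-conditioned.
    """
    p = model.params
    target = math.log(p.gamma_c) - math.log(p.gamma_m)

    def f(log_b1):
        return _steady_log_pore(log_b1, model) - target

    lo, hi = math.log(1e-12), math.log(1e12)
    return math.exp(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))


def quasistatic_from_kinetics(
    params: KineticParameters, M_0: float, B_T: float
) -> QuasiStaticParams:
    """Reduce a full kinetic parameter set to the one-variable model."""
    model = KineticModel(params)
    return QuasiStaticParams(
        M_0=M_0,
        M_s=params.sigma_M / params.delta_M,
        delta_M=params.delta_M,
        B_T=B_T,
        K_M=params.K_M,
        A=params.pore_size,
        K_C=calibrate_kc(model),
    )
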