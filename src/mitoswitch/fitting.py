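"""Constrained calibration of population parameters to survival curves.

The calibration is a two-stage, derivative-free least-squares procedure:

1. a large random search samples parameter vectors uniformly inside hard box
   bounds (uniform on a log scale for ratios, spreads, time constants and
   knockdown factors);
2. compass (pattern) search refines the lowest-SSE points, polling +/- steps
   along each coordinate of the transformed parameter vector with step
   halving, which guarantees monotone descent.

Hard bounds encode the experimental constraints: the Mcl-1 decay constant
stays inside its measured half-life interval, and protein-ratio medians stay
inside western-blot mean +/- 2 SD boxes.  Conditions (control, Mcl-1
knockdown, Bcl-xL knockdown) share every parameter except the knockdown
factor of the targeted protein.  Model curves inside the objective come from
deterministic quadrature so the objective is noise-free.

Also home to the single-exponential decay fitter used to turn Mcl-1
time-course measurements into half-life constraints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError
from .population import CellLinePopulation, SurvivalCurve, survival_curve_quadrature

__all__ = [
    "fit_decay",
    "FitProblem",
    "FitResult",
    "objective",
    "fit",
    "default_bounds",
]

#: Upper limit for the decay time constant when the data do not decay.
TAU_UPPER = 1e9

#: Parameters optimized by default, in vector order.  ``log`` marks
#: coordinates searched on a natural-log scale.
PARAM_SPEC = {
    "mu_m": {"log": False},
    "sigma_m": {"log": True},
    "mu_x": {"log": False},
    "sigma_x": {"log": True},
    "sigma_b": {"log": True},
    "tau_M": {"log": True},
    "tau_X": {"log": True},
    "theta_ref": {"log": True},
    "knockdown_m": {"log": True},
    "knockdown_x": {"log": True},
}

#: Which knockdown factor each non-control condition toggles.
CONDITION_TARGETS = {"control": None, "mcl1kd": "knockdown_m", "bclxlkd": "knockdown_x"}


# ---------------------------------------------------------------------------
# Exponential decay fitting (half-life constraints)
# ---------------------------------------------------------------------------

def fit_decay(timepoints, levels, return_half_life: bool = False):
    """Least-squares fit of f(t) = A_0 exp(-t/tau) to a decay time course.

    Returns ``(A_0, tau)``; with ``return_half_life=True`` the second value
    is the half-life tau*ln(2) instead.  Non-decaying data yield tau pinned
    at an upper limit, with a warning.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.size < 3 or t.size != y.size:
        raise ValidationError("need >= 3 (time, level) pairs")
    if np.any(y <= 0):
        raise ValidationError("levels must be positive")

    # log-linear regression gives the starting point
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        warnings.warn(
            "levels do not decay; tau pinned at upper limit",
            RuntimeWarning, stacklevel=2,
        )
        a0 = float(np.exp(intercept))
        return (a0, TAU_UPPER * math.log(2)) if return_half_life else (a0, TAU_UPPER)

    p0 = (math.exp(intercept), -1.0 / slope)
    popt, _ = curve_fit(
        lambda tt, a0, tau: a0 * np.exp(-tt / tau),
        t, y, p0=p0, bounds=([0.0, 0.0], [np.inf, TAU_UPPER]), maxfev=10000,
    )
    a0, tau = float(popt[0]), float(popt[1])
    return (a0, tau * math.log(2)) if return_half_life else (a0, tau)


# ---------------------------------------------------------------------------
# Fit problem definition
# ---------------------------------------------------------------------------

def default_bounds() -> dict[str, tuple[float, float]]:
    """Generic box bounds; tighten with measurement constraints per problem."""
    return {
        "mu_m": (math.log(0.1), math.log(1000.0)),
        "sigma_m": (0.05, 1.5),
        "mu_x": (math.log(0.01), math.log(100.0)),
        "sigma_x": (0.05, 1.5),
        "sigma_b": (0.05, 1.0),
        "tau_M": (0.5, 6.0),          # hours; replace with half-life bounds
        "tau_X": (4.0, 100.0),
        "theta_ref": (0.1, 10.0),
        "knockdown_m": (0.05, 0.5),   # plausible residual after RNAi
        "knockdown_x": (0.05, 0.5),
    }


@dataclass
class FitProblem:
    """Curves, bounds and fixed values defining one calibration problem.

    ``curves`` maps condition names (``control``, ``mcl1kd``, ``bclxlkd``)
    to corrected survival curves.  ``bounds`` gives finite (lo, hi) per free
    parameter; a parameter absent from ``bounds`` must appear in ``fixed``.
    """

    curves: dict[str, SurvivalCurve]
    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    quad_nodes: int = 32

    def __post_init__(self):
        unknown = set(self.curves) - set(CONDITION_TARGETS)
        if unknown:
            raise ValidationError(f"unknown conditions: {sorted(unknown)}")
        if not self.curves:
            raise ValidationError("need at least one survival curve")
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAM_SPEC:
                raise ValidationError(f"unknown parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValidationError(f"bounds for {name} must be finite, lo <= hi")
            if PARAM_SPEC[name]["log"] and lo <= 0:
                raise ValidationError(f"{name} is log-scaled; bounds must be > 0")
        missing = set(PARAM_SPEC) - set(self.bounds) - set(self.fixed)
        if missing:
            raise ValidationError(f"parameters neither bounded nor fixed: {sorted(missing)}")

    @property
    def free_names(self) -> list[str]:
        return [n for n in PARAM_SPEC if n in self.bounds]

    # --- transformed coordinates ------------------------------------------
    def to_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([
            math.log(params[n]) if PARAM_SPEC[n]["log"] else params[n]
            for n in self.free_names
        ])

    def from_vector(self, x: np.ndarray) -> dict[str, float]:
        out = dict(self.fixed)
        for name, xi in zip(self.free_names, x):
            out[name] = math.exp(xi) if PARAM_SPEC[name]["log"] else float(xi)
        return out

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.free_names:
            l, h = self.bounds[n]
            if PARAM_SPEC[n]["log"]:
                l, h = math.log(l), math.log(h)
            lo.append(l)
            hi.append(h)
        return np.array(lo), np.array(hi)


def _population(params: dict[str, float], condition: str) -> CellLinePopulation:
    target = CONDITION_TARGETS[condition]
    return CellLinePopulation(
        mu_m=params["mu_m"], sigma_m=params["sigma_m"],
        mu_x=params["mu_x"], sigma_x=params["sigma_x"],
        sigma_b=params["sigma_b"],
        tau_M=params["tau_M"], tau_X=params["tau_X"],
        theta_ref=params["theta_ref"],
        knockdown_m=params["knockdown_m"] if target == "knockdown_m" else 1.0,
        knockdown_x=params["knockdown_x"] if target == "knockdown_x" else 1.0,
    )


def predicted_curves(params: dict[str, float], problem: FitProblem) -> dict[str, SurvivalCurve]:
    """Noise-free model curves for every condition on the data grids."""
    return {
        cond: survival_curve_quadrature(
            _population(params, cond), curve.times, label=cond,
            n_nodes=problem.quad_nodes,
        )
        for cond, curve in problem.curves.items()
    }


def objective(params: dict[str, float], problem: FitProblem) -> float:
    """Sum of squared residuals between model and data curves."""
    sse = 0.0
    try:
        model = predicted_curves(params, problem)
    except (ValidationError, FloatingPointError):
        return 1e12  # penalty for an unevaluable parameter vector
    for cond, data in problem.curves.items():
        w = problem.weights.get(cond, 1.0)
        resid = model[cond].fraction - data.fraction
        resid = resid[np.isfinite(resid)]
        sse += w * float(np.dot(resid, resid))
    return sse


# ---------------------------------------------------------------------------
# Two-stage search
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Best-fit parameters with search provenance."""

    parameters: dict[str, float]
    sse: float
    trace: list[tuple[int, float]]
    restarts: pd.DataFrame

    def population(self, condition: str = "control") -> CellLinePopulation:
        return _population(self.parameters, condition)

    def to_text(self) -> str:
        lines = [f"sse = {self.sse:.6g}", "parameters:"]
        lines += [f"  {k} = {v:.6g}" for k, v in sorted(self.parameters.items())]
        lines.append("restarts:")
        lines.append(self.restarts.to_string(index=False))
        return "\n".join(lines)


def _compass_search(f, x0, lo, hi, step0=0.25, step_tol=1e-3, max_iter=500):
    """Coordinate pattern search with step halving; never accepts an ascent."""
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = f(x)
    step = float(step0)
    trace = [(0, fx)]
    for it in range(1, max_iter + 1):
        best_x, best_f = None, fx
        for i in range(len(x)):
            for s in (+step, -step):
                cand = x.copy()
                cand[i] = min(max(cand[i] + s, lo[i]), hi[i])
                if cand[i] == x[i]:
                    continue
                fc = f(cand)
                if fc < best_f:
                    best_x, best_f = cand, fc
        if best_x is None:
            step *= 0.5
            if step < step_tol:
                break
        else:
            x, fx = best_x, best_f
        trace.append((it, fx))
    return x, fx, trace


def fit(problem: FitProblem, n_random: int, n_starts: int, seed,
        step0: float = 0.25, step_tol: float = 1e-3, max_iter: int = 500) -> FitResult:
    """Two-stage constrained least squares.

    Stage 1 draws ``n_random`` parameter vectors uniformly in the transformed
    box; stage 2 runs compass search from the ``n_starts`` lowest-SSE points.
    Deterministic given ``seed``.
    """
    if not (n_random >= n_starts >= 1):
        raise ValidationError("need n_random >= n_starts >= 1")
    lo, hi = problem.vector_bounds()
    if np.any(hi < lo):
        raise ValidationError("empty search box")

    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(n_random, len(lo)))
    f = lambda x: objective(problem.from_vector(x), problem)
    sse0 = np.array([f(x) for x in X])
    order = np.argsort(sse0, kind="stable")[:n_starts]

    rows, best = [], None
    full_trace = []
    for rank, idx in enumerate(order):
        x_opt, f_opt, trace = _compass_search(
            f, X[idx], lo, hi, step0=step0, step_tol=step_tol, max_iter=max_iter
        )
        rows.append(
            {"start": rank, "initial_sse": sse0[idx], "final_sse": f_opt,
             **{f"param_{k}": v for k, v in problem.from_vector(x_opt).items()}}
        )
        if best is None or f_opt < best[1]:
            best = (x_opt, f_opt)
            full_trace = trace
    params = problem.from_vector(best[0])
    return FitResult(
        parameters=params, sse=best[1], trace=full_trace,
        restarts=pd.DataFrame(rows).sort_values("final_sse").reset_index(drop=True),
    )
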