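"""ODE models of Mcl-1-gated Bak pore formation and cytochrome-C release.

Two reaction networks share the same backbone -- first-order Mcl-1 turnover,
reversible sequestration of Bak monomer by Mcl-1, and a ladder of successive
dimerizations B_n + B_n <-> B_2n -- and differ only in the size ``A`` of the
oligomer that acts as the active mitochondrial membrane pore (A = 4 for the
tetramer model, A = 256 for the massively oligomeric model) and in the
pore-mediated CytC translocation constant.  CytC exchange is bilinear mass
action in the pore species:

    d[C_c]/dt = gamma_m * [B_A] * [C_m] - gamma_c * [C_c]

Total Bak (counted in subunits, including the Mcl-1:Bak complex) and total
CytC are conserved; both conservation laws are checked on every trajectory.

All concentrations are in nM and times in seconds unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import (
    AmbiguousCrossingError,
    IntegrationError,
    InvalidModelError,
    ValidationError,
)

__all__ = [
    "KineticParameters",
    "InitialState",
    "KineticModel",
    "Trajectory",
    "build_model",
    "simulate",
    "switch_duration",
    "momp_time",
    "crossing_time",
    "reference_parameters",
    "reference_initial_state",
]

#: Concentration floor below which a trajectory is considered invalid (nM).
NEGATIVE_FLOOR = -1e-9


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and pore size for one model variant.

    Rates carry units of nM/s (``sigma_M``), 1/s (first-order) or 1/nM/s
    (bimolecular).  ``pore_size`` must be a power of two >= 2, reachable by
    successive dimerizations from the monomer.
    """

    sigma_M: float
    delta_M: float
    alpha_M: float
    beta_M: float
    alpha_12: float
    beta_12: float
    alpha_24: float
    beta_24: float
    gamma_m: float
    gamma_c: float
    pore_size: int
    alpha_other: float = 1.0
    beta_other: float = 1.0

    def __post_init__(self):
        for name in (
            "sigma_M", "delta_M", "alpha_M", "beta_M", "alpha_12", "beta_12",
            "alpha_24", "beta_24", "gamma_m", "gamma_c", "alpha_other",
            "beta_other",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"rate {name}={value!r} must be finite and >= 0")
        A = self.pore_size
        if not isinstance(A, (int, np.integer)) or A < 2 or not _is_power_of_two(int(A)):
            raise InvalidModelError(
                f"pore size {A!r} is not reachable by successive dimerizations "
                "(must be a power of 2, >= 2)"
            )

    def ladder_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Association/dissociation rate per dimerization step (monomer up)."""
        n_steps = int(math.log2(self.pore_size))
        alphas = np.full(n_steps, self.alpha_other)
        betas = np.full(n_steps, self.beta_other)
        alphas[0], betas[0] = self.alpha_12, self.beta_12
        if n_steps > 1:
            alphas[1], betas[1] = self.alpha_24, self.beta_24
        return alphas, betas

    @property
    def K_M(self) -> float:
        """Mcl-1:Bak dissociation constant beta_M/alpha_M (nM)."""
        return self.beta_M / self.alpha_M


@dataclass(frozen=True)
class InitialState:
    """Initial concentrations (nM) for every species.

    ``B_species`` holds one concentration per Bak oligomer size
    (1, 2, 4, ..., A).
    """

    B_species: tuple[float, ...]
    M_free: float
    MB: float
    C_m: float
    C_c: float = 0.0

    def __post_init__(self):
        values = (*self.B_species, self.M_free, self.MB, self.C_m, self.C_c)
        if any(v < 0 or not np.isfinite(v) for v in values):
            raise ValidationError("initial concentrations must be finite and >= 0")

    def total_bak(self, sizes: np.ndarray) -> float:
        return float(np.dot(sizes, self.B_species) + self.MB)

    @property
    def total_cytc(self) -> float:
        return self.C_m + self.C_c


class KineticModel:
    """A compiled reaction network ready for integration.

    Species order: ``M, MB, B_1, B_2, ..., B_A, C_c, C_m``.
    """

    def __init__(self, params: KineticParameters):
        self.params = params
        self.n_steps = int(math.log2(params.pore_size))
        self.sizes = 2 ** np.arange(self.n_steps + 1)
        self.alphas, self.betas = params.ladder_rates()
        self.species = (
            ["M", "MB"]
            + [f"B_{n}" for n in self.sizes]
            + ["C_c", "C_m"]
        )
        self.model_tag = "Model I" if params.pore_size == 4 else (
            "Model II" if params.pore_size == 256 else f"A={params.pore_size}"
        )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def pack(self, init: InitialState) -> np.ndarray:
        if len(init.B_species) != len(self.sizes):
            raise ValidationError(
                f"initial state has {len(init.B_species)} Bak species, "
                f"model expects {len(self.sizes)}"
            )
        return np.array(
            [init.M_free, init.MB, *init.B_species, init.C_c, init.C_m]
        )

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        nb = len(self.sizes)
        M, MB = y[0], y[1]
        B = y[2 : 2 + nb]
        C_c, C_m = y[2 + nb], y[3 + nb]

        seq = p.alpha_M * M * B[0] - p.beta_M * MB
        dB = np.zeros(nb)
        for k in range(nb - 1):
            r = self.alphas[k] * B[k] * B[k] - self.betas[k] * B[k + 1]
            dB[k] -= 2.0 * r
            dB[k + 1] += r
        dB[0] -= seq
        flux = p.gamma_m * B[-1] * C_m - p.gamma_c * C_c

        dy = np.empty_like(y)
        dy[0] = p.sigma_M - p.delta_M * M - seq
        dy[1] = seq
        dy[2 : 2 + nb] = dB
        dy[2 + nb] = flux
        dy[3 + nb] = -flux
        return dy


@dataclass
class Trajectory:
    """Time-indexed concentrations from one integration."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: list[str]
    model_tag: str
    params: KineticParameters = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    @property
    def cytc_fraction(self) -> np.ndarray:
        C_c, C_m = self["C_c"], self["C_m"]
        return C_c / (C_c + C_m)

    def conservation_error(self) -> tuple[float, float]:
        """Max relative drift of total Bak and total CytC over the grid."""
        sizes = np.array([int(s[2:]) for s in self.species if s.startswith("B_")])
        B = np.stack([self[f"B_{n}"] for n in sizes], axis=1)
        bak = B @ sizes + self["MB"]
        cytc = self["C_c"] + self["C_m"]
        return (
            float(np.max(np.abs(bak - bak[0])) / bak[0]),
            float(np.max(np.abs(cytc - cytc[0])) / cytc[0]),
        )

    def to_frame(self):
        """Tidy export: columns time_s, species, concentration_nM."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, len(self.species)),
                "species": np.tile(self.species, n_t),
                "concentration_nM": self.states.ravel(),
            }
        )


def build_model(params: KineticParameters) -> KineticModel:
    """Compile the reaction network for the given parameters.

    The network contains Mcl-1 synthesis/degradation, reversible
    Mcl-1 + B_1 <-> MB sequestration, the dimerization ladder up to the pore
    size, and CytC exchange driven by the size-A species only.
    """
    return KineticModel(params)


def simulate(
    model: KineticModel,
    init: InitialState,
    horizon: float,
    grid: float = 10.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the network with a stiff solver and return the trajectory.

    ``horizon`` and ``grid`` are in seconds; the output grid only affects
    interpolation of switch metrics, not solver accuracy.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    if grid <= 0 or grid > horizon:
        raise ValidationError("grid step must be in (0, horizon]")

    y0 = model.pack(init)
    t_eval = np.arange(0.0, horizon + 0.5 * grid, grid)
    t_eval[-1] = min(t_eval[-1], horizon)
    sol = solve_ivp(
        model.rhs, (0.0, horizon), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        last_y = sol.y[:, -1] if sol.t.size else y0
        raise IntegrationError(
            f"stiff solver failed at t={last_t:.1f}s: {sol.message}",
            last_time=last_t, last_state=last_y,
        )

    states = sol.y.T
    min_c = states.min()
    if min_c < NEGATIVE_FLOOR:
        raise IntegrationError(
            f"concentration fell to {min_c:.3e} nM, below the tolerated floor",
            last_time=sol.t[-1], last_state=states[-1],
        )
    if min_c < 0:
        warnings.warn(
            f"small negative concentration {min_c:.2e} nM within solver tolerance",
            RuntimeWarning, stacklevel=2,
        )
    traj = Trajectory(sol.t, states, list(model.species), model.model_tag, model.params)
    return traj


def crossing_time(
    times: np.ndarray, values: np.ndarray, level: float, rel_tol: float = 1e-9
) -> float | None:
    """First time ``values`` reaches ``level``, by linear interpolation.

    Returns ``None`` if the level is never reached.  Raises
    :class:`AmbiguousCrossingError` when the series crosses the level upward
    more than once (non-monotone switch).
    """
    values = np.asarray(values, dtype=float)
    above = values >= level
    up = np.flatnonzero(~above[:-1] & above[1:])
    n_cross = len(up) + (1 if above[0] else 0)
    if not above.any():
        return None
    if n_cross > 1:
        # tolerate numerical jitter just below the level
        dips = values[np.flatnonzero(above[:-1] & ~above[1:]) + 1]
        if np.any(level - dips > rel_tol * max(abs(level), 1.0)):
            raise AmbiguousCrossingError(
                f"level {level} crossed {n_cross} times; crossing time ambiguous"
            )
    if above[0]:
        return float(times[0])
    i = up[0] + 1
    t0, t1 = times[i - 1], times[i]
    f0, f1 = values[i - 1], values[i]
    return float(t0 + (level - f0) / (f1 - f0) * (t1 - t0))


def momp_time(traj: Trajectory) -> float | None:
    """First time (s) the cytoplasmic CytC fraction reaches 1/2, or None."""
    return crossing_time(traj.times, traj.cytc_fraction, 0.5)


def switch_duration(traj: Trajectory) -> float | None:
    """Time (s) for the cytoplasmic CytC fraction to rise from 0.1 to 0.5.

    Returns None when the fraction never reaches 1/2.
    """
    frac = traj.cytc_fraction
    t50 = crossing_time(traj.times, frac, 0.5)
    if t50 is None:
        return None
    t10 = crossing_time(traj.times, frac, 0.1)
    return t50 - t10


# ---------------------------------------------------------------------------
# Bundled reference configuration
# ---------------------------------------------------------------------------

def _load_reference() -> dict:
    with resources.files("mitoswitch.data").joinpath("reference_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def reference_parameters(model: str = "II", **overrides) -> KineticParameters:
    """Reference rate constants for ``model`` 'I' (A=4) or 'II' (A=256)."""
    cfg = _load_reference()
    p = cfg["parameters"]
    model = model.upper().removeprefix("MODEL").strip()
    if model not in ("I", "II"):
        raise ValidationError(f"unknown model variant {model!r}; use 'I' or 'II'")
    gamma_m = p["gamma_m_model_I"] if model == "I" else p["gamma_m_model_II"]
    pore = cfg["pore_size"]["model_I" if model == "I" else "model_II"]
    params = KineticParameters(
        sigma_M=p["sigma_M"], delta_M=p["delta_M"],
        alpha_M=p["alpha_M"], beta_M=p["beta_M"],
        alpha_12=p["alpha_12"], beta_12=p["beta_12"],
        alpha_24=p["alpha_24"], beta_24=p["beta_24"],
        alpha_other=p["alpha_other"], beta_other=p["beta_other"],
        gamma_m=gamma_m, gamma_c=p["gamma_c"], pore_size=pore,
    )
    if overrides:
        params = replace(params, **overrides)
    return params


def reference_initial_state(pore_size: int) -> InitialState:
    """Reference initial concentrations for a ladder reaching ``pore_size``."""
    cfg = _load_reference()
    ic = cfg["initial_conditions"]
    n_species = int(math.log2(pore_size)) + 1
    return InitialState(
        B_species=(ic["B_oligomers"],) * n_species,
        M_free=ic["M"], MB=ic["MB"], C_m=ic["C_m"], C_c=ic["C_c"],
    )
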