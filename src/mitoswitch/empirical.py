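"""Exit-corrected mitotic survival curves from single-cell fate tables.

A cell in drug-induced mitotic arrest faces two competing, independent
fates: apoptotic death and mitotic exit (slippage).  Writing M(t) for the
number of cells still arrested, deaths and exits accrue with cause-specific
hazards delta(t) and epsilon(t).  Each hazard is estimated per time bin as

    hazard(bin) = events in bin / (cells at risk at bin start * bin width)

with cells leaving the risk set at their own fate time (each cell's clock
starts at its own arrest entry).  Under independence, exits act as censoring
for the death process and vice versa, so the death-only ("corrected")
survival curve and the cumulative exit curve are

    S(T) = exp(-sum_{bins<=T} delta * width)
    E(T) = 1 - exp(-sum_{bins<=T} epsilon * width).

Bins whose risk set is empty have undefined hazards; the gap is propagated
to the curves rather than silently filled.

Fate tables are plain delimited text with columns
``cell_id, entry_h, fate, fate_h`` where ``fate`` is one of
death / exit / censored and ``fate_h`` is time since that cell's arrest
entry, in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import SurvivalCurve

__all__ = [
    "FATES",
    "read_fate_table",
    "write_fate_table",
    "validate_fate_table",
    "HazardEstimate",
    "estimate_hazards",
    "corrected_survival",
    "exit_curve",
    "raw_survival",
]

FATES = ("death", "exit", "censored")


def validate_fate_table(tab: pd.DataFrame) -> pd.DataFrame:
    """Check vocabulary and nonnegativity; returns the validated frame."""
    required = {"cell_id", "entry_h", "fate", "fate_h"}
    missing = required - set(tab.columns)
    if missing:
        raise ValidationError(f"fate table missing columns: {sorted(missing)}")
    if len(tab) == 0:
        raise ValidationError("fate table has no cells")
    bad = set(tab["fate"]) - set(FATES)
    if bad:
        raise ValidationError(f"unknown fate labels: {sorted(bad)}")
    if (tab["fate_h"] < 0).any() or (tab["entry_h"] < 0).any():
        raise ValidationError("times must be >= 0")
    return tab


def read_fate_table(path) -> pd.DataFrame:
    return validate_fate_table(pd.read_csv(path, sep="\t"))


def write_fate_table(tab: pd.DataFrame, path) -> None:
    validate_fate_table(tab).to_csv(path, sep="\t", index=False)


@dataclass
class HazardEstimate:
    """Binned cause-specific hazard estimates (per hour)."""

    edges: np.ndarray          # bin edges, length n_bins + 1
    death_hazard: np.ndarray   # per-bin rate; NaN where undefined
    exit_hazard: np.ndarray
    at_risk: np.ndarray        # cells in arrest at each bin start
    n_cells: int

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def undefined(self) -> np.ndarray:
        return ~np.isfinite(self.death_hazard)


def estimate_hazards(tab: pd.DataFrame, bins) -> HazardEstimate:
    """Estimate the death and exit hazards on the given time grid.

    ``bins`` is either an array of bin edges (hours since arrest entry) or a
    scalar bin width, in which case edges cover all observed fate times.
    """
    tab = validate_fate_table(tab)
    t = tab["fate_h"].to_numpy(dtype=float)
    fate = tab["fate"].to_numpy()
    if bool(np.all((fate == "censored") & (t == 0))):
        raise ValidationError("every cell censored at t=0: nothing to estimate")

    if np.ndim(bins) == 0:
        width = float(bins)
        if width <= 0:
            raise ValidationError("bin width must be positive")
        upper = max(t.max(), width)
        edges = np.arange(0.0, upper + width, width)
        if edges[-1] < upper:
            edges = np.append(edges, edges[-1] + width)
    else:
        edges = np.asarray(bins, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if edges[0] > 0 or edges[-1] < t.max():
            raise ValidationError("bins must cover all observed fate times")

    n_bins = len(edges) - 1
    # a cell is at risk in a bin if its fate time is >= the bin start
    at_risk = (t[None, :] >= edges[:-1, None]).sum(axis=1)
    deaths = np.histogram(t[fate == "death"], bins=edges)[0]
    exits = np.histogram(t[fate == "exit"], bins=edges)[0]
    if at_risk[0] == 0:
        raise ValidationError("no cell at risk at time 0: degenerate fate table")

    widths = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        dh = np.where(at_risk > 0, deaths / (at_risk * widths), np.nan)
        eh = np.where(at_risk > 0, exits / (at_risk * widths), np.nan)
    return HazardEstimate(edges, dh, eh, at_risk, n_cells=len(tab))


def _cumulative_curve(h: HazardEstimate, hazard: np.ndarray) -> np.ndarray:
    """exp(-cumulative hazard) at each bin edge; NaN past an undefined bin
    that is followed by further events (interior gap)."""
    increments = hazard * h.widths
    cum = np.concatenate([[0.0], np.nancumsum(increments)])
    gap = np.concatenate([[False], np.isnan(increments)])
    past_gap = np.cumsum(gap) > 0
    surv = np.exp(-cum)
    surv[past_gap] = np.nan
    return surv


def corrected_survival(h: HazardEstimate, label: str = "") -> SurvivalCurve:
    """Death-only survival S(T), with exits treated as independent censoring."""
    surv = _cumulative_curve(h, h.death_hazard)
    return SurvivalCurve(
        h.edges, surv, label=label, source="empirical-corrected",
        n_effective=h.n_cells, gaps=np.isnan(surv),
    )


def exit_curve(h: HazardEstimate, label: str = "") -> SurvivalCurve:
    """Cumulative exit probability given alive: E(T) = 1 - exp(-cum hazard)."""
    surv = _cumulative_curve(h, h.exit_hazard)
    return SurvivalCurve(
        h.edges, 1.0 - surv, label=label, source="empirical-exit",
        n_effective=h.n_cells, gaps=np.isnan(surv),
    )


def raw_survival(tab: pd.DataFrame, grid) -> SurvivalCurve:
    """Uncorrected survival-in-arrest: fraction of cells that have neither
    died nor exited by T (the M(t)/M(0) curve of the cell-number model;
    censored cells count as still arrested).

    Because exits also deplete it, this curve lies at or below the
    exit-corrected death-only survival; used as a comparison baseline.
    """
    tab = validate_fate_table(tab)
    grid = np.asarray(grid, dtype=float)
    t = tab["fate_h"].to_numpy(dtype=float)
    gone = (tab["fate"] != "censored").to_numpy()
    frac = 1.0 - (gone[None, :] & (t[None, :] <= grid[:, None])).mean(axis=1)
    return SurvivalCurve(grid, frac, source="empirical-raw", n_effective=len(tab))
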