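"""Edge-trap catch profiles and exponential decay-constant fits.

For a corner release, catch is summarised along the two grid edges
adjacent to the release corner. The corner trap is T1; for each further
index t the two traps lying t-1 positions along the two edges are averaged
(they are mirror images across the release diagonal, hence exchangeable).
Interior traps and the far edges are excluded: they screen returning
movers rather than sampling outbound flux.

The decay constant k is the slope of ln(mean catch) on the trap index,
fitted by ordinary least squares over the bins with positive mean catch
(an exact exponential profile gives k exactly). A direct nonlinear
exponential fit on the raw means is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .engine import DataError, TrapGrid, UnfittableError, UsageError
from .scenarios import GridSpec, trap_id

logger = logging.getLogger("meandergrid")

__all__ = [
    "EdgeProfile",
    "DecayFit",
    "label_edge_traps",
    "aggregate_edge_catches",
    "fit_decay_constant",
]

MIN_BINS = 3  # fewest positive bins that still anchor a slope


@dataclass(frozen=True)
class EdgeProfile:
    """Mean catch per edge-trap index (T1 = corner nearest the release)."""

    indices: np.ndarray    # 1..n
    mean_catch: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.mean_catch > 0))

    @property
    def fittable(self) -> bool:
        return self.n_positive >= MIN_BINS


@dataclass(frozen=True)
class DecayFit:
    """Log-linear decay fit of an edge profile.

    ``k`` is per trap interval (index units, not metres); the standard
    curve is calibrated on the same axis, so the unit cancels on inversion.
    """

    k: float
    intercept: float
    r_squared: float
    n_bins_used: int
    k_se: float
    method: str = "loglinear"


def _resolve_shape(grid) -> tuple[int, int]:
    if isinstance(grid, tuple) and len(grid) == 2:
        return int(grid[0]), int(grid[1])
    if isinstance(grid, GridSpec):
        return grid.n_rows, grid.n_cols
    if isinstance(grid, TrapGrid):
        if not grid.has_lattice:
            raise UsageError("edge labelling needs a lattice trap grid")
        return grid.lattice_shape
    raise UsageError(f"cannot label edges on {type(grid).__name__}")


def label_edge_traps(
    grid, release_corner: tuple[int, int] = (0, 0)
) -> dict[str, int]:
    """Map trap id -> edge index (1-based) for the release-corner edges.

    ``release_corner`` is the (row, col) of the corner trap nearest the
    release point. Returns only the labelled edge traps; every other trap
    is interior for this analysis. Index 1 is the corner trap alone; index
    t >= 2 holds the two traps t-1 positions along each adjacent edge.
    """
    n_rows, n_cols = _resolve_shape(grid)
    cr, cc = release_corner
    if cr not in (0, n_rows - 1) or cc not in (0, n_cols - 1):
        raise UsageError(
            f"release corner {release_corner} is not a corner of a "
            f"{n_rows}x{n_cols} grid"
        )
    labels: dict[str, int] = {trap_id(cr, cc): 1}
    row_step = 1 if cr == 0 else -1
    col_step = 1 if cc == 0 else -1
    for d in range(1, n_cols):
        labels[trap_id(cr, cc + d * col_step)] = d + 1
    for d in range(1, n_rows):
        labels[trap_id(cr + d * row_step, cc)] = d + 1
    return labels


def aggregate_edge_catches(
    catches: Mapping[str, int], labels: Mapping[str, int]
) -> EdgeProfile:
    """Collapse per-trap catches into the T1..Tn edge profile.

    T1 is the corner trap's catch; each later index is the arithmetic mean
    of its (usually two) traps.
    """
    missing = [tid for tid in labels if tid not in catches]
    if missing:
        raise DataError(f"catches missing labelled traps: {missing}")
    n = max(labels.values())
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for tid, t in labels.items():
        sums[t - 1] += catches[tid]
        counts[t - 1] += 1
    profile = EdgeProfile(
        indices=np.arange(1, n + 1), mean_catch=sums / counts
    )
    if not profile.fittable:
        logger.warning(
            "edge profile has %d positive bins (<%d): unfittable",
            profile.n_positive,
            MIN_BINS,
        )
    return profile


def fit_decay_constant(
    profile: EdgeProfile, method: str = "loglinear"
) -> DecayFit:
    """Fit k from an edge profile.

    loglinear (default): OLS of ln(mean_catch) on the trap index over the
    positive bins; zero bins are dropped with a warning (ln 0 is undefined
    and imputation would bias k). nonlinear: least squares of
    a*exp(k*index) on the raw means. Raises UnfittableError when fewer
    than three positive bins remain.
    """
    y = np.asarray(profile.mean_catch, dtype=float)
    x = np.asarray(profile.indices, dtype=float)
    pos = y > 0
    n_used = int(pos.sum())
    if n_used < MIN_BINS:
        raise UnfittableError(
            f"need >= {MIN_BINS} positive bins, have {n_used}",
            profile=profile,
        )
    if n_used < len(y):
        logger.warning(
            "dropping %d zero-catch bin(s) from decay fit", len(y) - n_used
        )
    res = stats.linregress(x[pos], np.log(y[pos]))
    if method == "loglinear":
        return DecayFit(
            k=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            n_bins_used=n_used,
            k_se=float(res.stderr),
        )
    if method == "nonlinear":
        def model(t, a, k):
            return a * np.exp(k * t)

        p0 = (np.exp(res.intercept), res.slope)
        popt, pcov = optimize.curve_fit(
            model, x[pos], y[pos], p0=p0, maxfev=10000
        )
        resid = y[pos] - model(x[pos], *popt)
        ss_tot = float(np.sum((y[pos] - y[pos].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return DecayFit(
            k=float(popt[1]),
            intercept=float(np.log(popt[0])),
            r_squared=r2,
            n_bins_used=n_used,
            k_se=float(np.sqrt(pcov[1, 1])),
            method="nonlinear",
        )
    raise UsageError(f"unknown fit method {method!r}")
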