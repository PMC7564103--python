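"""Capture-vs-meander sweeps, optimum detection and target-density accounting.

A sweep runs replicate populations at each c.s.d. and records the mean and
SEM of total captures. The "optimal" c.s.d. is read off as the smallest
tested value whose mean capture is statistically tied with the sweep
maximum (within one pooled SEM of the difference) — well-defined both for
saturating curves, where capture plateaus at 100%, and for interior peaks
at low target density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    MeanderGridError,
    ParameterError,
    TrapGrid,
    TurnModel,
    WalkParams,
    simulate_population,
)

__all__ = [
    "SweepResult",
    "Optimum",
    "DensityReport",
    "run_capture_sweep",
    "find_optimal_csd",
    "target_density",
]


@dataclass(frozen=True)
class SweepResult:
    """Replicate capture totals across a c.s.d. grid."""

    csd_values: np.ndarray     # degrees, ascending
    captures: np.ndarray       # (n_csd, n_runs) total captures per run
    n_movers: int
    scenario_echo: dict

    @property
    def n_runs(self) -> int:
        return self.captures.shape[1]

    @property
    def mean_captures(self) -> np.ndarray:
        return self.captures.mean(axis=1)

    @property
    def sem_captures(self) -> np.ndarray:
        if self.n_runs < 2:
            return np.zeros(len(self.csd_values))
        return self.captures.std(axis=1, ddof=1) / np.sqrt(self.n_runs)

    def dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "csd_deg": self.csd_values,
                "mean_capture": self.mean_captures,
                "sem_capture": self.sem_captures,
                "n_runs": self.n_runs,
            }
        )


@dataclass(frozen=True)
class Optimum:
    """Outcome of the smallest-c.s.d.-attaining-max rule."""

    csd_deg: float | None
    boundary: bool = False
    note: str = ""


@dataclass(frozen=True)
class DensityReport:
    """Area of habitat per target (trap), under two box conventions.

    ``area_per_target`` uses the lattice-cell convention (bounding box of
    trap centres expanded by half a spacing per side, or the seeding
    rectangle for a single-trap arena); ``area_per_target_tight`` uses the
    tight centre-to-centre box. Both are reported because "targets per
    area" depends on where one draws the habitat boundary.
    """

    area_per_target: float
    area_per_target_tight: float | None = None
    reference_area_per_target: float | None = None

    @property
    def fold_change(self) -> float | None:
        if self.reference_area_per_target is None:
            return None
        return self.area_per_target / self.reference_area_per_target


def run_capture_sweep(
    scenario: tuple[TrapGrid, object],
    csd_values,
    n_runs: int,
    walk: dict | WalkParams,
    *,
    seed: int = 0,
) -> SweepResult:
    """Replicated capture totals for each c.s.d. value.

    ``walk`` gives n_movers/n_steps (its seed field, if any, is ignored:
    per-run seeds are spawned from ``seed`` in (c.s.d., run) order so every
    point of the sweep is independent yet reproducible).
    """
    csd_values = np.asarray(sorted(float(c) for c in csd_values))
    if csd_values.size == 0:
        raise ParameterError("csd_values must be non-empty")
    if isinstance(walk, WalkParams):
        n_movers, n_steps = walk.n_movers, walk.n_steps
        step_length = walk.step_length
    else:
        n_movers, n_steps = walk["n_movers"], walk["n_steps"]
        step_length = walk.get("step_length", 1.0)
    grid, release = scenario

    children = np.random.SeedSequence(seed).spawn(csd_values.size * n_runs)
    captures = np.zeros((csd_values.size, n_runs), dtype=float)
    for i, csd in enumerate(csd_values):
        for r in range(n_runs):
            child = children[i * n_runs + r]
            run_seed = int(child.generate_state(1)[0] % (2**31))
            params = WalkParams(
                n_movers=n_movers,
                n_steps=n_steps,
                step_length=step_length,
                seed=run_seed,
            )
            res = simulate_population(TurnModel(csd), params, grid, release)
            captures[i, r] = res.n_captured
    return SweepResult(
        csd_values=csd_values,
        captures=captures,
        n_movers=n_movers,
        scenario_echo={
            "n_traps": len(grid),
            "n_movers": n_movers,
            "n_steps": n_steps,
            "n_runs": n_runs,
            "seed": seed,
        },
    )


def find_optimal_csd(sweep: SweepResult) -> Optimum:
    """Smallest tested c.s.d. statistically tied with the sweep maximum.

    The noise scale is one pooled SEM — the RMS of the per-point SEMs, a
    single sweep-level figure. A point is tied with the maximum when its
    mean capture is within one pooled SEM of the maximum mean; a sweep
    whose whole max-min spread is inside that band yields no optimum; an
    optimum at the largest tested c.s.d. is flagged as a boundary solution.
    """
    if len(sweep.csd_values) < 3:
        raise ParameterError("sweep needs >= 3 c.s.d. points")
    means = sweep.mean_captures
    sems = sweep.sem_captures
    i_max = int(np.argmax(means))
    pooled = float(np.sqrt(np.mean(sems**2)))
    if means[i_max] - means.min() < pooled:
        return Optimum(csd_deg=None, note="flat sweep: no optimum resolvable")
    tied = means >= means[i_max] - pooled
    i_opt = int(np.nonzero(tied)[0][0])
    boundary = i_opt == len(means) - 1
    return Optimum(
        csd_deg=float(sweep.csd_values[i_opt]),
        boundary=boundary,
        note="optimum at sweep boundary" if boundary else "",
    )


def target_density(
    scenario: tuple[TrapGrid, object],
    *,
    reference_area_per_target: float | None = None,
) -> DensityReport:
    """Square units of habitat per trap for a scenario.

    Lattice grids use the bounding box of trap centres expanded by half a
    spacing per side (each trap owns one lattice cell); the tight
    centre-to-centre box is reported alongside. A single-trap arena uses
    its uniform seeding rectangle.
    """
    grid, release = scenario
    n_traps = len(grid)
    if grid.has_lattice:
        n_rows, n_cols = grid.lattice_shape
        sp = grid.lattice_spacing
        cell_area = (n_rows * sp) * (n_cols * sp)
        tight = None
        if n_rows > 1 and n_cols > 1:
            tight = ((n_rows - 1) * sp) * ((n_cols - 1) * sp)
        return DensityReport(
            area_per_target=cell_area / n_traps,
            area_per_target_tight=(tight / n_traps) if tight else None,
            reference_area_per_target=reference_area_per_target,
        )
    rect = getattr(release, "rect", None)
    if rect is None:
        raise MeanderGridError(
            "target density needs a lattice grid or a seeding rectangle"
        )
    xmin, ymin, xmax, ymax = rect
    area = (xmax - xmin) * (ymax - ymin)
    return DensityReport(
        area_per_target=area / n_traps,
        reference_area_per_target=reference_area_per_target,
    )
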