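"""Geometry builders for the trapping-grid experiments.

Three canonical layouts:

* ``corner5x5`` — 5 x 5 grid of 2 x 2-unit traps spaced 15 units apart,
  movers released at a point 10 units outside the corner trap along the
  grid diagonal (the field mark-release-recapture layout; 1 unit ~ 1 m).
* ``center7x7`` — 7 x 7 grid spaced 20 units, movers released near the
  central trap (half a spacing off-centre so the release point is outside
  every trap).
* ``lowdensity`` — a single trap at the centre of a 1000 x 600-unit
  seeding rectangle in unbounded space; movers start uniformly in the
  rectangle (one target per 600,000 square units).

Coordinates are continuous Cartesian with the origin at the centre of trap
(row 0, col 0); rows increase along +y, columns along +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GeometryError, TrapGrid, TrapRegion

__all__ = [
    "GridSpec",
    "ReleaseSpec",
    "trap_id",
    "build_trap_grid",
    "build_corner_release_scenario",
    "build_center_release_scenario",
    "build_low_density_scenario",
    "SCENARIO_BUILDERS",
    "geometry_dataframe",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice of square traps."""

    n_rows: int
    n_cols: int
    spacing: float
    trap_side: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid needs at least one row and column")
        if (
            min(self.n_rows, self.n_cols) > 1
            and self.spacing <= self.trap_side
        ):
            raise GeometryError(
                f"spacing {self.spacing} must exceed trap side "
                f"{self.trap_side} (traps would overlap)"
            )


def trap_id(row: int, col: int) -> str:
    return f"r{row}c{col}"


@dataclass(frozen=True)
class ReleaseSpec:
    """Where movers start.

    mode="point": all movers at ``point``. mode="uniform_rect": independent
    uniform positions inside ``rect`` = (xmin, ymin, xmax, ymax), with
    rejection of any draw landing inside a trap of ``avoid``.
    """

    mode: str
    point: tuple[float, float] | None = None
    rect: tuple[float, float, float, float] | None = None
    avoid: TrapGrid | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "point":
            return np.tile(np.asarray(self.point, dtype=float), (n, 1))
        if self.mode == "uniform_rect":
            xmin, ymin, xmax, ymax = self.rect
            out = np.empty((n, 2), dtype=float)
            need = np.ones(n, dtype=bool)
            while np.any(need):
                m = int(need.sum())
                cand = np.column_stack(
                    (
                        rng.uniform(xmin, xmax, m),
                        rng.uniform(ymin, ymax, m),
                    )
                )
                if self.avoid is not None:
                    bad = self.avoid.contains_points(cand)
                else:
                    bad = np.zeros(m, dtype=bool)
                slots = np.nonzero(need)[0]
                ok = slots[~bad]
                out[ok] = cand[~bad]
                need[ok] = False
            return out
        raise GeometryError(f"unknown release mode {self.mode!r}")


def build_trap_grid(spec: GridSpec) -> TrapGrid:
    """Materialise a GridSpec into a TrapGrid with lattice acceleration."""
    ox, oy = spec.origin
    traps = [
        TrapRegion(
            center_x=ox + c * spec.spacing,
            center_y=oy + r * spec.spacing,
            side=spec.trap_side,
            id=trap_id(r, c),
            row=r,
            col=c,
        )
        for r in range(spec.n_rows)
        for c in range(spec.n_cols)
    ]
    return TrapGrid(
        traps,
        lattice_origin=spec.origin,
        lattice_spacing=spec.spacing,
        lattice_shape=(spec.n_rows, spec.n_cols),
    )


def build_corner_release_scenario(
    spacing: float = 15.0,
    trap_side: float = 2.0,
    n: int = 5,
    release_offset: float = 10.0,
) -> tuple[TrapGrid, ReleaseSpec]:
    """n x n grid with a point release outside the (0, 0) corner trap.

    The release point sits on the grid's main diagonal, ``release_offset``
    units outward from the corner trap's centre — the symmetry axis that
    makes the two edge traps at each index exchangeable, which the decay
    analysis exploits by averaging them.
    """
    if release_offset <= trap_side / 2.0:
        raise GeometryError(
            "release_offset places the release point inside the corner trap"
        )
    spec = GridSpec(n_rows=n, n_cols=n, spacing=spacing, trap_side=trap_side)
    grid = build_trap_grid(spec)
    u = release_offset / np.sqrt(2.0)
    release = ReleaseSpec(mode="point", point=(-u, -u))
    return grid, release


def build_center_release_scenario(
    spacing: float = 20.0,
    trap_side: float = 2.0,
    n: int = 7,
    release_rule: float = 0.1,
) -> tuple[TrapGrid, ReleaseSpec]:
    """n x n grid with a point release near the central trap.

    ``release_rule`` is the release offset in units of the spacing, applied
    along +x from the central trap's centre. The default (0.1 spacing = 2
    units for the canonical grid) puts the release one step length outside
    the central trap's edge — as near the grid centre as a mover can start
    without being inside a trap. It is a sensitivity knob: larger offsets
    (up to 0.5, midway to the +x neighbour) delay first trap contact and
    thin the high-meander capture plateau.
    """
    spec = GridSpec(n_rows=n, n_cols=n, spacing=spacing, trap_side=trap_side)
    grid = build_trap_grid(spec)
    mid = (n - 1) // 2
    cx = mid * spacing + release_rule * spacing
    cy = mid * spacing
    point = (cx, cy)
    if grid.contains_points(np.array([point]))[0]:
        raise GeometryError("central release point falls inside a trap")
    release = ReleaseSpec(mode="point", point=point)
    return grid, release


def build_low_density_scenario(
    arena_w: float = 1000.0,
    arena_h: float = 600.0,
    trap_side: float = 2.0,
) -> tuple[TrapGrid, ReleaseSpec]:
    """Single trap at the centre of a uniform seeding rectangle.

    The rectangle spans (0, 0)-(arena_w, arena_h); space itself stays
    unbounded, the rectangle only bounds the starting positions.
    """
    trap = TrapRegion(
        center_x=arena_w / 2.0,
        center_y=arena_h / 2.0,
        side=trap_side,
        id="center",
    )
    grid = TrapGrid([trap])
    release = ReleaseSpec(
        mode="uniform_rect", rect=(0.0, 0.0, arena_w, arena_h), avoid=grid
    )
    return grid, release


SCENARIO_BUILDERS = {
    "corner5x5": build_corner_release_scenario,
    "center7x7": build_center_release_scenario,
    "lowdensity": build_low_density_scenario,
}


def geometry_dataframe(grid: TrapGrid):
    """Trap layout table (trap_id, row, col, x, y) for plotting/exports."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "trap_id": t.id,
                "row": t.row,
                "col": t.col,
                "x": t.center_x,
                "y": t.center_y,
            }
            for t in grid.traps
        ]
    )
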