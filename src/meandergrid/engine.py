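"""Correlated-random-walk engine with absorbing square traps.

Movers step through unbounded 2-D space with a fixed step length. Each
step's heading is the previous heading plus a turn angle drawn from a
zero-centred Gaussian whose spread is expressed as a circular standard
deviation (c.s.d.) in degrees. Axis-aligned square traps absorb any mover
whose step segment touches them; captured movers are frozen and counted.

The per-step capture test is segment-vs-square intersection (slab method),
not endpoint-in-square, so a mover cannot tunnel through a trap corner in a
single step. An endpoint-only mode is available via ``capture_mode`` for
sensitivity comparisons.

Randomness: one master seed per run; ``numpy.random.SeedSequence(seed)``
feeds a single ``default_rng`` stream that draws, in order, the release
positions (when sampled), the initial headings, then one turn vector per
step. Higher-level drivers that need several independent runs spawn child
seed sequences from the master seed, so every result is reproducible from
one integer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("meandergrid")

__all__ = [
    "MeanderGridError",
    "ParameterError",
    "GeometryError",
    "UsageError",
    "DataError",
    "UnfittableError",
    "TurnModel",
    "WalkParams",
    "TrapRegion",
    "TrapGrid",
    "MoverState",
    "SimResult",
    "draw_turn_angles",
    "wrap_angles_deg",
    "advance_step",
    "detect_capture",
    "simulate_population",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MeanderGridError(Exception):
    """Base class for all package errors."""


class ParameterError(MeanderGridError, ValueError):
    """A numeric parameter is outside its valid domain."""


class GeometryError(MeanderGridError, ValueError):
    """Trap/release geometry is inconsistent (overlap, release inside trap)."""


class UsageError(MeanderGridError, ValueError):
    """An operation was called in an invalid state or with invalid ids."""


class DataError(MeanderGridError, ValueError):
    """Input tables are malformed (missing cells, negative counts...)."""


class UnfittableError(MeanderGridError, ValueError):
    """Too few usable bins to fit a decay constant; carries the profile."""

    def __init__(self, message: str, profile=None):
        super().__init__(message)
        self.profile = profile


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurnModel:
    """Gaussian turn-angle law.

    Parameters
    ----------
    csd_deg:
        Circular standard deviation of turn angles, degrees, >= 0. Turns are
        drawn from Normal(0, csd_deg**2) and wrapped into (-180, 180]. For
        the spreads of interest (<= 80 deg) the wrapped and unwrapped
        circular s.d. are indistinguishable in practice.
    mean_turn_deg:
        Centre of the turn distribution; 0 means straight-ahead centring
        (the classical correlated random walk).
    """

    csd_deg: float
    mean_turn_deg: float = 0.0

    def __post_init__(self):
        if self.csd_deg < 0:
            raise ParameterError(f"csd_deg must be >= 0, got {self.csd_deg}")


@dataclass(frozen=True)
class WalkParams:
    """Population-level walk parameters.

    step_length is in the same distance units as the trap geometry
    (1 unit ~ 1 m in the field mapping).
    """

    n_movers: int
    n_steps: int
    step_length: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_movers < 1:
            raise ParameterError(f"n_movers must be >= 1, got {self.n_movers}")
        if self.n_steps < 0:
            raise ParameterError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.step_length <= 0:
            raise ParameterError(
                f"step_length must be > 0, got {self.step_length}"
            )


@dataclass(frozen=True)
class TrapRegion:
    """Axis-aligned square absorbing trap.

    Occupies the closed square [center - side/2, center + side/2] on both
    axes. ``row``/``col`` are optional lattice indices for grid-built traps.
    """

    center_x: float
    center_y: float
    side: float = 2.0
    id: str = "trap"
    row: int | None = None
    col: int | None = None

    def __post_init__(self):
        if self.side <= 0:
            raise ParameterError(f"trap side must be > 0, got {self.side}")

    @property
    def half(self) -> float:
        return self.side / 2.0

    def contains(self, x: float, y: float, pad: float = 0.0) -> bool:
        h = self.half + pad
        return (abs(x - self.center_x) <= h) and (abs(y - self.center_y) <= h)


class TrapGrid:
    """A collection of non-overlapping square traps, optionally on a lattice.

    When the traps form a regular lattice (equal side, constant spacing)
    the grid records origin/spacing/shape so the engine can find the only
    candidate trap for a short step by rounding coordinates instead of
    testing every trap.
    """

    def __init__(
        self,
        traps: Sequence[TrapRegion],
        *,
        lattice_origin: tuple[float, float] | None = None,
        lattice_spacing: float | None = None,
        lattice_shape: tuple[int, int] | None = None,
    ):
        if len(traps) == 0:
            raise GeometryError("a TrapGrid needs at least one trap")
        self.traps = list(traps)
        self.ids = [t.id for t in self.traps]
        if len(set(self.ids)) != len(self.ids):
            raise GeometryError("trap ids must be unique")
        self.centers = np.array(
            [[t.center_x, t.center_y] for t in self.traps], dtype=float
        )
        sides = np.array([t.side for t in self.traps], dtype=float)
        self.halves = sides / 2.0
        self._check_overlap()
        self.lattice_origin = lattice_origin
        self.lattice_spacing = lattice_spacing
        self.lattice_shape = lattice_shape
        if lattice_shape is not None:
            n_rows, n_cols = lattice_shape
            # row-major index table: lattice (row, col) -> trap index
            self._lattice_index = np.full((n_rows, n_cols), -1, dtype=int)
            for i, t in enumerate(self.traps):
                if t.row is None or t.col is None:
                    raise GeometryError(
                        "lattice grids need row/col on every trap"
                    )
                self._lattice_index[t.row, t.col] = i
        else:
            self._lattice_index = None

    def _check_overlap(self):
        # pairwise separation test; closed squares must not intersect
        n = len(self.traps)
        for i in range(n):
            for j in range(i + 1, n):
                dx = abs(self.centers[i, 0] - self.centers[j, 0])
                dy = abs(self.centers[i, 1] - self.centers[j, 1])
                lim = self.halves[i] + self.halves[j]
                if dx <= lim and dy <= lim:
                    raise GeometryError(
                        f"traps {self.ids[i]!r} and {self.ids[j]!r} overlap"
                    )

    def __len__(self) -> int:
        return len(self.traps)

    @property
    def has_lattice(self) -> bool:
        return self._lattice_index is not None

    def contains_points(self, xy: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Boolean mask: which points lie inside (or on) any trap square."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.abs(xy[:, None, :] - self.centers[None, :, :])
        lim = self.halves[None, :, None] + pad
        return np.any(np.all(d <= lim, axis=2), axis=1)

    def trap_for_position(self, x: float, y: float) -> int:
        """Index of the trap containing (x, y), or -1."""
        mask = self.contains_points(np.array([[x, y]]))
        if not mask[0]:
            return -1
        d = np.abs(np.array([x, y]) - self.centers)
        inside = np.all(d <= self.halves[:, None], axis=1)
        return int(np.nonzero(inside)[0][0])


@dataclass
class MoverState:
    """Scalar mover state for the single-step API."""

    x: float
    y: float
    heading_deg: float
    captured_by: str | None = None
    capture_step: int | None = None


@dataclass
class SimResult:
    """Outcome of one population run.

    Invariant: ``sum(catches.values()) + len(free_positions) == n_movers``.
    """

    catches: dict[str, int]
    free_positions: np.ndarray           # (n_free, 2) final positions
    capture_positions: np.ndarray        # (n_caught, 2) entry points
    capture_trap_ids: list[str]          # trap id per captured mover
    capture_steps: np.ndarray            # 1-based step index per capture
    params_echo: dict

    @property
    def n_captured(self) -> int:
        return int(sum(self.catches.values()))

    @property
    def n_movers(self) -> int:
        return self.n_captured + len(self.free_positions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "catches": self.catches,
                "n_captured": self.n_captured,
                "n_free": int(len(self.free_positions)),
                "params": self.params_echo,
            },
            indent=2,
            sort_keys=True,
        )

    def catches_dataframe(self, grid: TrapGrid):
        """Per-trap catch table (trap_id, row, col, x, y, catch)."""
        import pandas as pd

        rows = []
        for t in grid.traps:
            rows.append(
                {
                    "trap_id": t.id,
                    "row": t.row,
                    "col": t.col,
                    "x": t.center_x,
                    "y": t.center_y,
                    "catch": self.catches.get(t.id, 0),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Turn-angle sampling and single-step kinematics
# ---------------------------------------------------------------------------

def wrap_angles_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) into the interval (-180, 180]."""
    a = np.asarray(angles, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def draw_turn_angles(
    model: TurnModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` turn angles (degrees) from the Gaussian turn law.

    Values are Normal(mean_turn_deg, csd_deg**2) wrapped into (-180, 180].
    csd_deg = 0 yields exactly ``mean_turn_deg`` for every draw.
    """
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    if model.csd_deg == 0:
        return np.full(n, float(model.mean_turn_deg))
    raw = rng.normal(model.mean_turn_deg, model.csd_deg, size=n)
    return wrap_angles_deg(raw)


def advance_step(
    state: MoverState, turn_deg: float, step_length: float
) -> MoverState:
    """Advance a single mover by one step.

    The new heading is the old heading plus the turn (mod 360); the
    displacement has Euclidean norm ``step_length``.
    """
    if state.captured_by is not None:
        raise UsageError("cannot advance a captured mover")
    heading = (state.heading_deg + turn_deg) % 360.0
    if heading == 360.0:  # float wrap of a tiny negative turn
        heading = 0.0
    rad = np.deg2rad(heading)
    return MoverState(
        x=state.x + step_length * np.cos(rad),
        y=state.y + step_length * np.sin(rad),
        heading_deg=heading,
    )


# ---------------------------------------------------------------------------
# Segment / square capture geometry
# ---------------------------------------------------------------------------

def _segment_square_entry(
    p: np.ndarray, q: np.ndarray, centers: np.ndarray, halves: np.ndarray
) -> np.ndarray:
    """Entry parameter t in [0, 1] where segment p->q first meets a square.

    Vectorised slab (Liang-Barsky) test. ``p``/``q`` broadcast against
    ``centers`` on the leading axes; returns +inf where there is no
    intersection. Squares are closed, so grazing contact counts.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    lo = centers - halves[..., None]
    hi = centers + halves[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - p) / d
        t2 = (hi - p) / d
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    zero = d == 0
    if np.any(zero):
        inside = (p >= lo) & (p <= hi)
        tmin = np.where(zero, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(zero, np.where(inside, np.inf, -np.inf), tmax)
    tenter = np.max(tmin, axis=-1)
    texit = np.min(tmax, axis=-1)
    hit = (tenter <= texit) & (texit >= 0.0) & (tenter <= 1.0)
    t = np.clip(tenter, 0.0, 1.0)
    return np.where(hit, t, np.inf)


def detect_capture(
    prev: tuple[float, float],
    nxt: tuple[float, float],
    traps: Sequence[TrapRegion] | TrapGrid,
) -> str | None:
    """Return the id of the first trap the segment prev->nxt touches.

    If the segment crosses several traps the one whose entry point is
    nearest ``prev`` wins (physical first contact). Returns None when the
    segment misses every trap.
    """
    grid = traps if isinstance(traps, TrapGrid) else TrapGrid(list(traps))
    p = np.asarray(prev, dtype=float)
    q = np.asarray(nxt, dtype=float)
    t = _segment_square_entry(p, q, grid.centers, grid.halves)
    i = int(np.argmin(t))
    if not np.isfinite(t[i]):
        return None
    return grid.ids[i]


def _first_hit_lattice(
    grid: TrapGrid, p: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-hit trap index and entry t per mover via lattice rounding.

    Valid when step_length < spacing/2 - side/2: any segment touching a
    trap then has both endpoints rounding to that trap's lattice node, so
    only the nodes nearest the two endpoints need testing.
    """
    ox, oy = grid.lattice_origin
    sp = grid.lattice_spacing
    n_rows, n_cols = grid.lattice_shape
    n = p.shape[0]
    best_t = np.full(n, np.inf)
    best_i = np.full(n, -1, dtype=int)
    for pt in (p, q):
        col = np.rint((pt[:, 0] - ox) / sp).astype(int)
        row = np.rint((pt[:, 1] - oy) / sp).astype(int)
        valid = (row >= 0) & (row < n_rows) & (col >= 0) & (col < n_cols)
        if not np.any(valid):
            continue
        idx = np.full(n, -1, dtype=int)
        idx[valid] = grid._lattice_index[row[valid], col[valid]]
        valid &= idx >= 0
        if not np.any(valid):
            continue
        vi = np.nonzero(valid)[0]
        t = _segment_square_entry(
            p[vi], q[vi], grid.centers[idx[vi]], grid.halves[idx[vi]]
        )
        better = t < best_t[vi]
        bw = vi[better]
        best_t[bw] = t[better]
        best_i[bw] = idx[vi][better]
    return best_i, best_t


def _first_hit_generic(
    grid: TrapGrid, p: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-hit trap index and entry t by testing every trap (broadcast)."""
    t = _segment_square_entry(
        p[:, None, :], q[:, None, :],
        grid.centers[None, :, :], grid.halves[None, :],
    )
    best = np.argmin(t, axis=1)
    best_t = t[np.arange(len(p)), best]
    best_i = np.where(np.isfinite(best_t), best, -1)
    return best_i, best_t


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def _resolve_release(release, n: int, rng: np.random.Generator) -> np.ndarray:
    """Release -> (n, 2) start positions.

    Accepts an (x, y) point, an (n, 2) array, or any object with a
    ``sample(n, rng)`` method (scenarios.ReleaseSpec).
    """
    if hasattr(release, "sample"):
        pos = np.asarray(release.sample(n, rng), dtype=float)
    else:
        arr = np.asarray(release, dtype=float)
        if arr.shape == (2,):
            pos = np.tile(arr, (n, 1))
        elif arr.ndim == 2 and arr.shape == (n, 2):
            pos = arr.copy()
        else:
            raise ParameterError(
                "release must be an (x, y) point, an (n_movers, 2) array, "
                "or provide sample(n, rng)"
            )
    return pos


def simulate_population(
    model: TurnModel,
    params: WalkParams,
    traps: Sequence[TrapRegion] | TrapGrid,
    release,
    *,
    capture_mode: str = "segment",
) -> SimResult:
    """Run a full population of correlated random walkers through the traps.

    Each mover starts at its release position with an independent heading
    uniform on [0, 360); the first step follows that heading with no turn,
    and every later step adds a fresh Gaussian turn. A mover whose step
    touches a trap is frozen at the entry point and credited to that trap
    at that step index. Space is unbounded: there is no outer wall.

    capture_mode="segment" (default) tests the whole step segment against
    trap squares; "endpoint" tests only the step's end point (faster,
    slightly leaky at trap corners).
    """
    if capture_mode not in ("segment", "endpoint"):
        raise ParameterError(f"unknown capture_mode {capture_mode!r}")
    grid = traps if isinstance(traps, TrapGrid) else TrapGrid(list(traps))

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_movers
    pos = _resolve_release(release, n, rng)
    if np.any(grid.contains_points(pos)):
        raise GeometryError("release position(s) inside a trap square")

    heading = rng.uniform(0.0, 360.0, size=n)

    # lattice fast path is exact only while a step cannot span the gap
    # between a trap's influence zone and the next lattice cell
    use_lattice = (
        grid.has_lattice
        and params.step_length
        < grid.lattice_spacing / 2.0 - float(np.max(grid.halves))
    )
    first_hit = _first_hit_lattice if use_lattice else _first_hit_generic

    active = np.ones(n, dtype=bool)
    captured_trap = np.full(n, -1, dtype=int)
    capture_step = np.zeros(n, dtype=int)
    capture_xy = np.zeros((n, 2), dtype=float)

    L = params.step_length
    for step in range(1, params.n_steps + 1):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        if step > 1:
            turns = draw_turn_angles(model, idx.size, rng)
            heading[idx] = (heading[idx] + turns) % 360.0
        rad = np.deg2rad(heading[idx])
        p = pos[idx]
        q = p + L * np.column_stack((np.cos(rad), np.sin(rad)))

        if capture_mode == "segment":
            hit_i, hit_t = first_hit(grid, p, q)
        else:
            inside = grid.contains_points(q)
            hit_i = np.full(idx.size, -1, dtype=int)
            hit_t = np.full(idx.size, np.inf)
            for j in np.nonzero(inside)[0]:
                hit_i[j] = grid.trap_for_position(q[j, 0], q[j, 1])
                hit_t[j] = 1.0

        caught = hit_i >= 0
        if np.any(caught):
            ci = idx[caught]
            t = hit_t[caught][:, None]
            capture_xy[ci] = p[caught] + t * (q[caught] - p[caught])
            captured_trap[ci] = hit_i[caught]
            capture_step[ci] = step
            active[ci] = False
            pos[ci] = capture_xy[ci]
        free = ~caught
        pos[idx[free]] = q[free]

    catches = {tid: 0 for tid in grid.ids}
    caught_mask = captured_trap >= 0
    for ti in captured_trap[caught_mask]:
        catches[grid.ids[ti]] += 1

    echo = {
        "csd_deg": model.csd_deg,
        "mean_turn_deg": model.mean_turn_deg,
        "n_movers": params.n_movers,
        "n_steps": params.n_steps,
        "step_length": params.step_length,
        "seed": params.seed,
        "n_traps": len(grid),
        "capture_mode": capture_mode,
    }
    return SimResult(
        catches=catches,
        free_positions=pos[~caught_mask].copy(),
        capture_positions=capture_xy[caught_mask].copy(),
        capture_trap_ids=[grid.ids[i] for i in captured_trap[caught_mask]],
        capture_steps=capture_step[caught_mask].copy(),
        params_echo=echo,
    )
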