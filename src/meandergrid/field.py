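"""Field-style catch tables: parsing, orientation, analysis, fixtures.

A field replicate is a complete R x C grid of per-trap counts from one
mark-release-recapture batch, released outside one of the four grid
corners. Tables are stored long-form in CSV with columns

    replicate_id, row, col, catch, release_corner[, release_size, label]

where row 0 is the northernmost trap row and col 0 the westernmost column,
and release_corner is one of NW/NE/SW/SE. Analysis first rotates/reflects
every table so its release corner sits at the canonical NW position
(row 0, col 0), then runs the edge-trap decay fit and inverts the k through
a standard curve. Because no raw field tables are publicly available, the
fixture generator produces synthetic replicates by simulating the
corner-release scenario, optionally binomially thinned to mimic imperfect
recapture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import StandardCurve, invert
from .decay import aggregate_edge_catches, fit_decay_constant, label_edge_traps
from .engine import (
    DataError,
    MeanderGridError,
    TurnModel,
    UnfittableError,
    WalkParams,
    simulate_population,
)
from .scenarios import build_corner_release_scenario, trap_id

logger = logging.getLogger("meandergrid")

__all__ = [
    "CORNERS",
    "CANONICAL_CORNER",
    "CatchTable",
    "FieldSummary",
    "read_catch_tables",
    "write_catch_tables",
    "orient_to_release_corner",
    "analyze_field",
    "generate_field_fixture",
]

CORNERS = ("NW", "NE", "SW", "SE")
CANONICAL_CORNER = "NW"
DEFAULT_HIST_EDGES = np.arange(10.0, 70.0, 5.0)  # 5-degree bins, 10-65


@dataclass(frozen=True)
class CatchTable:
    """One replicate's complete grid of trap catches."""

    replicate_id: str
    counts: np.ndarray            # (n_rows, n_cols) non-negative ints
    release_corner: str
    release_size: int | None = None
    label: str | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise DataError(
                f"replicate {self.replicate_id!r}: counts must be 2-D"
            )
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise DataError(
                f"replicate {self.replicate_id!r}: negative count at "
                f"row {r}, col {c}"
            )
        if self.release_corner not in CORNERS:
            raise DataError(
                f"replicate {self.replicate_id!r}: invalid release corner "
                f"{self.release_corner!r} (expected one of {CORNERS})"
            )
        if (
            self.release_size is not None
            and counts.sum() > self.release_size
        ):
            raise DataError(
                f"replicate {self.replicate_id!r}: total catch "
                f"{int(counts.sum())} exceeds release size "
                f"{self.release_size}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class FieldSummary:
    """Across-replicate summary of decay constants and meander estimates."""

    replicate_ids: list[str]
    replicate_k: np.ndarray
    replicate_csd: np.ndarray
    mean_k: float
    sem_k: float
    mean_csd: float
    sem_csd: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    csd_range: tuple[float, float]
    excluded: list[str]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "mean_k": self.mean_k,
            "sem_k": self.sem_k,
            "mean_csd": self.mean_csd,
            "sem_csd": self.sem_csd,
            "csd_range": list(self.csd_range),
            "replicate_k": self.replicate_k.tolist(),
            "replicate_csd": self.replicate_csd.tolist(),
            "hist_edges": self.hist_edges.tolist(),
            "hist_counts": self.hist_counts.tolist(),
            "excluded": self.excluded,
        }


def read_catch_tables(path) -> list[CatchTable]:
    """Parse a long-form catch CSV into validated CatchTables.

    Every replicate must cover its full grid exactly once per cell; errors
    name the offending replicate and cell.
    """
    df = pd.read_csv(path)
    required = {"replicate_id", "row", "col", "catch", "release_corner"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"catch CSV missing columns: {sorted(missing)}")
    tables = []
    for rid, grp in df.groupby("replicate_id", sort=False):
        rid = str(rid)
        n_rows = int(grp["row"].max()) + 1
        n_cols = int(grp["col"].max()) + 1
        counts = np.full((n_rows, n_cols), -1, dtype=int)
        for _, rec in grp.iterrows():
            r, c = int(rec["row"]), int(rec["col"])
            if r < 0 or c < 0:
                raise DataError(
                    f"replicate {rid!r}: negative grid index ({r}, {c})"
                )
            if counts[r, c] != -1:
                raise DataError(
                    f"replicate {rid!r}: duplicate cell row {r}, col {c}"
                )
            catch = int(rec["catch"])
            if catch < 0:
                raise DataError(
                    f"replicate {rid!r}: negative count at row {r}, col {c}"
                )
            counts[r, c] = catch
        holes = np.argwhere(counts == -1)
        if len(holes):
            r, c = holes[0]
            raise DataError(
                f"replicate {rid!r}: missing cell row {r}, col {c}"
            )
        corners = grp["release_corner"].unique()
        if len(corners) != 1:
            raise DataError(
                f"replicate {rid!r}: inconsistent release corner"
            )
        release_size = None
        if "release_size" in grp.columns and grp["release_size"].notna().any():
            release_size = int(grp["release_size"].iloc[0])
        label = None
        if "label" in grp.columns and grp["label"].notna().any():
            label = str(grp["label"].iloc[0])
        tables.append(
            CatchTable(
                replicate_id=rid,
                counts=counts,
                release_corner=str(corners[0]),
                release_size=release_size,
                label=label,
            )
        )
    return tables


def write_catch_tables(tables: list[CatchTable], path) -> None:
    """Write CatchTables back to the long-form CSV schema."""
    rows = []
    for t in tables:
        n_rows, n_cols = t.shape
        for r in range(n_rows):
            for c in range(n_cols):
                rows.append(
                    {
                        "replicate_id": t.replicate_id,
                        "row": r,
                        "col": c,
                        "catch": int(t.counts[r, c]),
                        "release_corner": t.release_corner,
                        "release_size": t.release_size,
                        "label": t.label,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _corner_transform(counts: np.ndarray, corner: str) -> np.ndarray:
    """Flip a grid so ``corner`` maps to NW. Each map is an involution."""
    if corner == "NW":
        return counts.copy()
    if corner == "NE":
        return counts[:, ::-1].copy()
    if corner == "SW":
        return counts[::-1, :].copy()
    if corner == "SE":
        return counts[::-1, ::-1].copy()
    raise DataError(f"invalid corner {corner!r}")


def orient_to_release_corner(table: CatchTable) -> CatchTable:
    """Rotate/reflect a table so its release corner is at NW (row 0, col 0)."""
    return CatchTable(
        replicate_id=table.replicate_id,
        counts=_corner_transform(table.counts, table.release_corner),
        release_corner=CANONICAL_CORNER,
        release_size=table.release_size,
        label=table.label,
    )


def _counts_to_catch_dict(counts: np.ndarray) -> dict[str, int]:
    n_rows, n_cols = counts.shape
    return {
        trap_id(r, c): int(counts[r, c])
        for r in range(n_rows)
        for c in range(n_cols)
    }


def analyze_field(
    tables: list[CatchTable],
    curve: StandardCurve,
    *,
    hist_edges: np.ndarray = DEFAULT_HIST_EDGES,
) -> FieldSummary:
    """Per-replicate decay fits and meander estimates, summarised.

    Each table is oriented to the canonical corner, collapsed to its edge
    profile, fitted for k, and inverted through ``curve``. Replicates with
    too few positive bins are excluded (and reported); all of them failing
    is an error.
    """
    if not tables:
        raise DataError("no catch tables to analyze")
    ids, ks, csds, excluded = [], [], [], []
    for table in tables:
        oriented = orient_to_release_corner(table)
        labels = label_edge_traps(oriented.shape, release_corner=(0, 0))
        profile = aggregate_edge_catches(
            _counts_to_catch_dict(oriented.counts), labels
        )
        try:
            fit = fit_decay_constant(profile)
        except UnfittableError:
            logger.warning(
                "replicate %s unfittable; excluded", table.replicate_id
            )
            excluded.append(table.replicate_id)
            continue
        ids.append(table.replicate_id)
        ks.append(fit.k)
        csds.append(invert(curve, fit.k).csd_deg)
    if not ids:
        raise MeanderGridError("all replicates unfittable")
    k = np.asarray(ks)
    csd = np.asarray(csds)
    n = len(k)
    sem_k = float(k.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    sem_csd = float(csd.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    hist_counts, edges = np.histogram(csd, bins=hist_edges)
    return FieldSummary(
        replicate_ids=ids,
        replicate_k=k,
        replicate_csd=csd,
        mean_k=float(k.mean()),
        sem_k=sem_k,
        mean_csd=float(csd.mean()),
        sem_csd=sem_csd,
        hist_edges=edges,
        hist_counts=hist_counts,
        csd_range=(float(csd.min()), float(csd.max())),
        excluded=excluded,
    )


def generate_field_fixture(
    true_csd: float,
    n_replicates: int,
    *,
    release_size: int = 800,
    recapture_p: float = 1.0,
    n_steps: int = 400,
    seed: int = 0,
) -> list[CatchTable]:
    """Synthetic field replicates from the corner-release simulation.

    Each replicate releases ``release_size`` movers at true c.s.d.
    ``true_csd`` into the 5x5 corner scenario for ``n_steps`` steps, then
    thins every trap's catch binomially with probability ``recapture_p``
    (1.0 = perfect recapture). Release corners cycle through NW/NE/SW/SE,
    with counts flipped to match, so downstream orientation is exercised.
    The output round-trips through ``write_catch_tables`` /
    ``read_catch_tables``.
    """
    grid, release = build_corner_release_scenario()
    n_rows, n_cols = grid.lattice_shape
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    tables = []
    for i in range(n_replicates):
        child = children[i]
        run_seed = int(child.generate_state(1)[0] % (2**31))
        params = WalkParams(
            n_movers=release_size, n_steps=n_steps, seed=run_seed
        )
        result = simulate_population(
            TurnModel(true_csd), params, grid, release
        )
        counts = np.zeros((n_rows, n_cols), dtype=int)
        for t in grid.traps:
            counts[t.row, t.col] = result.catches[t.id]
        if recapture_p < 1.0:
            thin_rng = np.random.default_rng(child.spawn(1)[0])
            counts = thin_rng.binomial(counts, recapture_p)
        corner = CORNERS[i % len(CORNERS)]
        tables.append(
            CatchTable(
                replicate_id=f"rep{i:03d}",
                counts=_corner_transform(counts, corner),
                release_corner=corner,
                release_size=release_size,
                label=f"synthetic csd={true_csd:g}",
            )
        )
    return tables
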