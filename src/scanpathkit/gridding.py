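"""Data-driven dwell-time grids sized from DBSCAN core-point radii.

Rather than imposing researcher-defined regions, the stimulus is divided
into a regular grid whose cell size is derived from the density structure of
the pooled fixations: DBSCAN is run over a descending ladder of candidate
radii, and the smallest radius at which at least one *core point* exists
(a point with >= ``min_pts`` neighbours within ``eps``, itself included)
sets the base cell dimension as the core-point *diameter*.  Cells are then
stretched to tile the stimulus exactly, so they may be rectangular but each
side is at least the base dimension.  Using the same grid for every group
makes per-cell dwell totals directly comparable.

DBSCAN itself is delegated to scikit-learn with the Euclidean metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .io import Fixation

__all__ = [
    "ClusterLabels",
    "GridSpec",
    "DwellGrid",
    "DEFAULT_EPS_LADDER",
    "DEFAULT_MIN_PTS",
    "fit_dbscan",
    "derive_core_radius",
    "make_grid",
    "bin_dwell",
    "group_dwell_diff",
]

#: descending candidate core-point radii, in stimulus pixels
DEFAULT_EPS_LADDER = (64.0, 48.0, 32.0, 24.0, 16.0, 12.0, 8.0)
DEFAULT_MIN_PTS = 5

NOISE = -1


@dataclass(frozen=True)
class ClusterLabels:
    """DBSCAN output: per-point cluster index (-1 = noise) and core flag."""

    labels: np.ndarray
    core: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))


@dataclass(frozen=True)
class GridSpec:
    """A regular grid tiling one stimulus.

    ``base_dimension`` is the core-point diameter the cells were sized from;
    cells are stretched so ``n_cols * cell_width`` equals the stimulus width
    exactly (likewise rows/height), hence each cell side >= base dimension.
    """

    width: float
    height: float
    n_cols: int
    n_rows: int
    cell_width: float
    cell_height: float
    base_dimension: float

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing (x, y); None if out of bounds.

        Cells are half-open; a point exactly on the stimulus's right or
        bottom edge is assigned to the last cell.
        """
        if not (0 <= x <= self.width and 0 <= y <= self.height):
            return None
        col = min(int(x // self.cell_width), self.n_cols - 1)
        row = min(int(y // self.cell_height), self.n_rows - 1)
        return row, col


@dataclass(frozen=True)
class DwellGrid:
    """Total fixation duration (ms) per grid cell, plus out-of-bounds tally."""

    grid: GridSpec
    values: np.ndarray
    excluded_count: int = 0
    excluded_duration: float = 0.0

    @property
    def argmax_cell(self) -> tuple[int, int]:
        """(row, col) of the cell with the largest dwell total."""
        r, c = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(r), int(c)


def fit_dbscan(
    points: Sequence[tuple[float, float]] | np.ndarray,
    eps: float,
    min_pts: int,
) -> ClusterLabels:
    """Standard DBSCAN over 2-D points with the Euclidean metric.

    Core points have at least ``min_pts`` points (themselves included)
    within ``eps``; clusters are maximal density-connected sets; remaining
    points are labelled noise (-1).
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    if min_pts < 1:
        raise ValueError(f"min_pts must be >= 1, got {min_pts}")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return ClusterLabels(np.empty(0, dtype=int), np.empty(0, dtype=bool))
    model = DBSCAN(eps=eps, min_samples=min_pts).fit(pts)
    core = np.zeros(len(pts), dtype=bool)
    core[model.core_sample_indices_] = True
    return ClusterLabels(model.labels_.astype(int), core)


def derive_core_radius(
    points: Sequence[tuple[float, float]] | np.ndarray,
    min_pts: int = DEFAULT_MIN_PTS,
    eps_candidates: Sequence[float] = DEFAULT_EPS_LADDER,
) -> float:
    """Smallest candidate radius at which at least one core point exists.

    Candidates must be positive and strictly decreasing.  Core-point
    existence is monotone in ``eps``, so the candidates are probed from the
    smallest upward and the first that yields a core point is returned.  If
    no candidate qualifies the largest is returned with a warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("derive_core_radius requires at least one point")
    cands = list(eps_candidates)
    if not cands:
        raise ValueError("eps_candidates must be non-empty")
    if any(c <= 0 for c in cands) or any(b >= a for a, b in zip(cands, cands[1:])):
        raise ValueError("eps_candidates must be positive and strictly decreasing")
    tree = cKDTree(pts)
    for eps in reversed(cands):  # smallest first
        counts = tree.query_ball_point(pts, r=eps, return_length=True)
        if np.any(counts >= min_pts):
            return float(eps)
    warnings.warn(
        f"no candidate radius yields a core point at min_pts={min_pts}; "
        f"falling back to the largest candidate {cands[0]}",
        stacklevel=2,
    )
    return float(cands[0])


def make_grid(stim_w: float, stim_h: float, core_radius: float) -> GridSpec:
    """Size a grid from a core-point radius.

    The base cell dimension is the core-point diameter ``2 * core_radius``.
    Column count is ``floor(stim_w / base)`` (at least 1) and cells are
    stretched to ``stim_w / n_cols`` so they tile the width exactly;
    likewise for rows.  A base dimension exceeding the smaller stimulus side
    degenerates to a single-cell grid with a warning.
    """
    if core_radius <= 0:
        raise ValueError(f"core_radius must be > 0, got {core_radius}")
    if stim_w <= 0 or stim_h <= 0:
        raise ValueError("stimulus dimensions must be positive")
    base = 2.0 * core_radius
    if base > min(stim_w, stim_h):
        warnings.warn(
            f"base dimension {base} exceeds stimulus {stim_w}x{stim_h}; "
            "using a single-cell grid",
            stacklevel=2,
        )
        return GridSpec(stim_w, stim_h, 1, 1, stim_w, stim_h, base)
    n_cols = max(1, int(stim_w // base))
    n_rows = max(1, int(stim_h // base))
    return GridSpec(
        stim_w, stim_h, n_cols, n_rows, stim_w / n_cols, stim_h / n_rows, base
    )


def bin_dwell(fixations: Sequence[Fixation], grid: GridSpec) -> DwellGrid:
    """Accumulate each fixation's full duration into the cell containing it.

    Cells are half-open; a point on an interior boundary goes to the
    higher-index cell, and the stimulus's right/bottom edge belongs to the
    last cell.  Out-of-bounds fixations are counted and their duration
    tallied separately, so total duration is conserved.
    """
    values = np.zeros((grid.n_rows, grid.n_cols))
    excluded_count = 0
    excluded_duration = 0.0
    for f in fixations:
        cell = grid.cell_of(f.x, f.y)
        if cell is None:
            excluded_count += 1
            excluded_duration += f.duration
        else:
            values[cell] += f.duration
    return DwellGrid(grid, values, excluded_count, excluded_duration)


class DwellDiff(NamedTuple):
    """Cellwise difference a - b between two dwell grids on one GridSpec."""

    diff: np.ndarray
    argmax_a: tuple[int, int]
    argmax_b: tuple[int, int]


def group_dwell_diff(grid_a: DwellGrid, grid_b: DwellGrid) -> DwellDiff:
    """Cellwise dwell difference between two groups on the same grid."""
    if grid_a.grid != grid_b.grid:
        raise ValueError("dwell grids use different GridSpecs")
    return DwellDiff(
        grid_a.values - grid_b.values, grid_a.argmax_cell, grid_b.argmax_cell
    )
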