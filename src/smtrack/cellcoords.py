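"""Normalized cell coordinates and intensity profiles.

To compare localization across cells of different sizes and orientations,
positions are mapped into a normalized frame: one pole is translated to the
origin, the pole axis is rotated onto x, and coordinates are divided by the
cell length and width so that u (long axis) and v (short axis) both span
0..1 for points inside the outline.  Pole labeling is arbitrary, so
long-axis distributions may also be pole-folded (u -> min(u, 1-u)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellOutline
from .synthetic import ImageStack
from .tracks import Track

__all__ = [
    "NormalizedPoint",
    "NucleoidProfile",
    "normalize_coordinates",
    "track_mean_positions",
    "axis_histograms",
    "fold_long_axis",
    "nucleoid_profile",
    "average_profiles",
]

STANDARD_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class NormalizedPoint:
    cell_id: int
    u: float  # long-axis fraction
    v: float  # short-axis fraction
    source: str = "localization"  # trajectory-mean | focus | localization


@dataclass
class NucleoidProfile:
    """Mean long-axis intensity profile, min-max normalized to [0, 1]."""

    grid: np.ndarray
    intensity: np.ndarray
    n_cells: int


def normalize_coordinates(
    points: np.ndarray, cell: CellOutline, source: str = "localization"
) -> list[NormalizedPoint]:
    """Map (n, 2) μm positions into the cell's normalized (u, v) frame.

    pole_a maps to u = 0, pole_b to u = 1; the short-axis midline is
    v = 0.5 with the outline spanning 0..1 across the maximal width.
    """
    if cell.length <= 0:
        raise ValueError("zero-length cell")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    ax = cell.axis_unit
    rel = pts - cell.pole_a
    u = (rel @ ax) / cell.length
    v = (rel @ np.array([-ax[1], ax[0]])) / cell.width + 0.5
    return [
        NormalizedPoint(cell_id=cell.cell_id, u=float(ui), v=float(vi), source=source)
        for ui, vi in zip(u, v)
    ]


def track_mean_positions(tracks: list[Track]) -> dict[int, np.ndarray]:
    """Mean position per track, grouped by cell: cell_id -> (n, 2) μm."""
    out: dict[int, list] = {}
    for t in tracks:
        out.setdefault(t.cell_id, []).append(t.mean_position())
    return {cid: np.array(v) for cid, v in out.items()}


def fold_long_axis(u: np.ndarray) -> np.ndarray:
    """Pole-unsigned long-axis coordinate min(u, 1-u)."""
    u = np.asarray(u, dtype=float)
    return np.minimum(u, 1.0 - u)


def axis_histograms(
    norm_points: list[NormalizedPoint], n_bins: int = 50
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Density-normalized histograms of u and v on [0, 1].

    Returns ((u_centers, u_density), (v_centers, v_density)).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    u = np.array([p.u for p in norm_points])
    v = np.array([p.v for p in norm_points])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    du, _ = np.histogram(np.clip(u, 0, 1 - 1e-12), bins=edges, density=True)
    dv, _ = np.histogram(np.clip(v, 0, 1 - 1e-12), bins=edges, density=True)
    return (centers, du), (centers, dv)


def nucleoid_profile(
    projection: np.ndarray,
    cell: CellOutline,
    pixel_size: float,
    origin: tuple = (0.0, 0.0),
    grid: np.ndarray = STANDARD_GRID,
) -> np.ndarray:
    """Long-axis centerline intensity profile of one cell on a standard grid.

    The pole-to-pole centerline is sampled at pixel pitch; each sample's
    coordinate is rounded to the nearest pixel, whose intensity is taken.
    Long-axis positions are normalized by the cell length and linearly
    interpolated onto ``grid``.
    """
    grid = np.asarray(grid)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must lie within [0, 1]")
    n_samples = max(2, int(np.ceil(cell.length / pixel_size)) + 1)
    u = np.linspace(0.0, 1.0, n_samples)
    x, y = cell.uv_to_xy(u, np.full_like(u, 0.5))
    col = np.round((x - origin[0]) / pixel_size - 0.5).astype(int)
    row = np.round((y - origin[1]) / pixel_size - 0.5).astype(int)
    h, w = projection.shape
    if col.min() < 0 or col.max() >= w or row.min() < 0 or row.max() >= h:
        raise ValueError("cell centerline exits the image")
    intensity = projection[row, col].astype(float)
    return np.interp(grid, u, intensity)


def average_profiles(
    profiles: list[np.ndarray], grid: np.ndarray = STANDARD_GRID
) -> NucleoidProfile:
    """Pointwise mean of single-cell profiles, then min-max normalized so the
    relative intensity spans exactly [0, 1] (idempotent on normalized input)."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    arr = np.vstack(profiles)
    mean = arr.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        mean = (mean - lo) / (hi - lo)
    else:
        mean = np.zeros_like(mean)
    return NucleoidProfile(grid=np.asarray(grid), intensity=mean, n_cells=len(profiles))
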