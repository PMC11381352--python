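"""Point-source detection and trajectory linking.

Detection fits candidate local maxima with symmetric 2D Gaussian
approximations of the PSF (free parameters: centroid x/y, width, amplitude,
background) inside each cell outline, and keeps a spot only if a one-sided
t-type test of the fitted amplitude against its standard error (from the
fit's residuals and Jacobian) rejects at significance level alpha — so
smaller alpha demands a higher signal-to-noise ratio.  Replisome foci are
detected the same way on an average projection, with an extra requirement
that the fitted background exceed the camera offset (2065 counts), which
removes false positives outside cells.

Linking solves, per frame pair, an optimal one-to-one assignment (minimum
total squared displacement) among spot pairs within a per-particle Brownian
search radius — ``multiplier × sqrt(4 D̂ Δframes)`` pixels from the
particle's running mean squared frame displacement, clipped to configured
bounds; unmatched particles may bridge a single missing frame when gaps are
allowed.  Nearest-neighbor density does not expand the radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import least_squares, linear_sum_assignment

from .geometry import CellOutline
from .synthetic import FociSet, ImageStack
from .tracks import Track

__all__ = [
    "Spot",
    "DetectionParams",
    "LinkingParams",
    "average_projection",
    "detect_spots",
    "detect_stack",
    "call_foci",
    "link_tracks",
]

log = logging.getLogger(__name__)


@dataclass
class Spot:
    frame: int
    x: float  # μm
    y: float  # μm
    psf_width: float  # px
    amplitude: float  # counts
    background: float  # counts
    cell_id: int = -1
    p_value: float = math.nan


@dataclass
class DetectionParams:
    """alpha: amplitude-significance level (1e-5 short-, 1e-6 long-exposure);
    min_background: foci-only floor on the fitted background (camera offset)."""

    alpha: float = 1e-5
    min_background: float | None = None
    fit_radius: int = 4  # px half-size of the fit window
    candidate_nsigma: float = 2.0  # pre-filter: local maxima this far above noise

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LinkingParams:
    """u-track-style linker settings.  Bounds are in pixels."""

    max_gap: int = 1  # 0 for long exposure
    min_track_len: int = 2
    min_analysis_len: int = 5
    brownian_multiplier: float = 5.0
    search_radius_bounds: tuple = (1.0, 10.0)  # (3.0 upper for long exposure)

    def __post_init__(self) -> None:
        lo, hi = self.search_radius_bounds
        if not (0 < lo <= hi):
            raise ValueError("search radius bounds must satisfy 0 < lower <= upper")
        if self.brownian_multiplier <= 0:
            raise ValueError("brownian_multiplier must be positive")


def average_projection(stack, n_frames: int) -> np.ndarray:
    """Pixel-wise mean of the first ``n_frames`` frames, floating point."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.shape[0] < n_frames:
        raise ValueError(
            f"stack has {data.shape[0]} frames but {n_frames} are required"
        )
    return data[:n_frames].astype(float).mean(axis=0)


def _gauss2d(params, jj, ii):
    a, x0, y0, s, b = params
    return b + a * np.exp(-((jj - x0) ** 2 + (ii - y0) ** 2) / (2 * s**2))


def _fit_spot(image, row, col, radius):
    """Fit a symmetric 2D Gaussian in a window around (row, col).

    Returns (amp, col0, row0, sigma, bg, p_value) or None on a degenerate
    fit.  Coordinates are pixel indices (sub-pixel)."""
    h, w = image.shape
    i0, i1 = max(row - radius, 0), min(row + radius + 1, h)
    j0, j1 = max(col - radius, 0), min(col + radius + 1, w)
    win = image[i0:i1, j0:j1].astype(float)
    if win.size < 12:
        return None
    ii, jj = np.mgrid[i0:i1, j0:j1]
    b0 = float(win.min())
    a0 = float(win.max() - b0)
    if a0 <= 0:
        return None
    x0 = [a0, float(col), float(row), 1.3, b0]
    lb = [0.0, j0 - 0.5, i0 - 0.5, 0.3, -np.inf]
    ub = [np.inf, j1 - 0.5, i1 - 0.5, float(radius * 2 + 1), np.inf]

    def resid(p):
        return (_gauss2d(p, jj, ii) - win).ravel()

    try:
        res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=200)
    except Exception:
        return None
    a, cx, cy, s, b = res.x
    dof = win.size - 5
    if dof <= 0:
        return None
    sd = math.sqrt(2 * res.cost / dof)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        log.debug("degenerate spot fit at (%d, %d): singular curvature", row, col)
        return None
    se_a = sd * math.sqrt(max(cov[0, 0], 0))
    if se_a == 0:
        return None
    t = a / se_a
    pval = float(stats.t.sf(t, dof))
    return a, cx, cy, s, b, pval


def detect_spots(
    image: np.ndarray,
    cell: CellOutline,
    params: DetectionParams = DetectionParams(),
    pixel_size: float = 0.106,
    origin: tuple = (0.0, 0.0),
    frame: int = 0,
) -> list[Spot]:
    """Detect sub-pixel spots inside one cell outline.

    Candidate pixels are local maxima of a lightly smoothed image above the
    robust noise floor; each is Gaussian-fit and kept if its amplitude is
    significant at level alpha.  Nearby duplicates keep the most
    significant fit.
    """
    image = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(image, 1.0)
    bg = np.median(smooth)
    noise = 1.4826 * np.median(np.abs(smooth - bg))
    ismax = ndimage.maximum_filter(smooth, size=3) == smooth
    cand = ismax & (smooth > bg + params.candidate_nsigma * max(noise, 1e-9))
    rows, cols = np.nonzero(cand)
    if len(rows):
        x = origin[0] + (cols + 0.5) * pixel_size
        y = origin[1] + (rows + 0.5) * pixel_size
        inside = cell.contains_xy(x, y)
        rows, cols = rows[inside], cols[inside]
    spots: list[Spot] = []
    for r, c in zip(rows, cols):
        out = _fit_spot(image, int(r), int(c), params.fit_radius)
        if out is None:
            continue
        a, cx, cy, s, b, pval = out
        if pval >= params.alpha:
            continue
        sx = origin[0] + (cx + 0.5) * pixel_size
        sy = origin[1] + (cy + 0.5) * pixel_size
        if not bool(cell.contains_xy(sx, sy)):
            continue
        spots.append(
            Spot(
                frame=frame,
                x=float(sx),
                y=float(sy),
                psf_width=float(s),
                amplitude=float(a),
                background=float(b),
                cell_id=cell.cell_id,
                p_value=pval,
            )
        )
    # merge duplicates closer than one pixel, keeping the most significant
    spots.sort(key=lambda s: s.p_value)
    kept: list[Spot] = []
    for s in spots:
        if all(math.hypot(s.x - k.x, s.y - k.y) > pixel_size for k in kept):
            kept.append(s)
    return kept


def detect_stack(
    stack: ImageStack,
    cells: list[CellOutline],
    params: DetectionParams = DetectionParams(),
) -> list[Spot]:
    """Run detect_spots on every frame and cell of a movie."""
    out: list[Spot] = []
    for f in range(stack.n_frames):
        for cell in cells:
            out.extend(
                detect_spots(
                    stack.data[f],
                    cell,
                    params,
                    pixel_size=stack.pixel_size,
                    origin=stack.origin,
                    frame=f,
                )
            )
    return out


def call_foci(
    projection: np.ndarray,
    cells: list[CellOutline],
    params: DetectionParams = DetectionParams(alpha=1e-5, min_background=2065.0),
    pixel_size: float = 0.106,
    origin: tuple = (0.0, 0.0),
) -> list[FociSet]:
    """Replisome foci from an average projection: spot detection per cell,
    then rejection of spots whose fitted background is not above the camera
    offset floor."""
    out = []
    floor = params.min_background if params.min_background is not None else -np.inf
    for cell in cells:
        spots = [
            s
            for s in detect_spots(projection, cell, params, pixel_size, origin)
            if s.background > floor
        ]
        out.append(
            FociSet(
                cell_id=cell.cell_id,
                centroids=np.array([[s.x, s.y] for s in spots]).reshape(-1, 2),
                widths=np.array([s.psf_width * pixel_size for s in spots]),
                amplitudes=np.array([s.amplitude for s in spots]),
                backgrounds=np.array([s.background for s in spots]),
            )
        )
    return out


class _Active:
    __slots__ = ("spots", "d_hat_sum", "d_hat_n")

    def __init__(self, spot: Spot):
        self.spots = [spot]
        self.d_hat_sum = 0.0  # accumulated squared per-frame displacement, μm²
        self.d_hat_n = 0

    @property
    def last(self) -> Spot:
        return self.spots[-1]

    def radius_um(self, lag: int, p: LinkingParams, pixel_size: float) -> float:
        lo, hi = p.search_radius_bounds
        if self.d_hat_n == 0:
            r_px = hi  # bootstrap: new particles get the upper bound
        else:
            msd_per_frame = self.d_hat_sum / self.d_hat_n  # = 4 D̂ Δt, μm²
            r_px = p.brownian_multiplier * math.sqrt(msd_per_frame * lag) / pixel_size
        return min(max(r_px, lo), hi) * pixel_size

    def add(self, spot: Spot):
        prev = self.last
        lag = spot.frame - prev.frame
        d2 = (spot.x - prev.x) ** 2 + (spot.y - prev.y) ** 2
        self.d_hat_sum += d2 / lag
        self.d_hat_n += 1
        self.spots.append(spot)


def _assign(track_list, spot_list, costs, no_link):
    """Optimal assignment with birth/death: returns list of (ti, si) links."""
    n_t, n_s = len(track_list), len(spot_list)
    big = 1e12
    size = n_t + n_s
    c = np.full((size, size), big)
    c[:n_t, :n_s] = costs
    for i in range(n_t):
        c[i, n_s + i] = no_link  # track continues unlinked (death/gap)
    for j in range(n_s):
        c[n_t + j, j] = no_link  # spot starts a new track (birth)
    c[n_t:, n_s:] = 0.0
    rows, cols = linear_sum_assignment(c)
    links = []
    for r, col in zip(rows, cols):
        if r < n_t and col < n_s and c[r, col] < no_link:
            links.append((r, col))
    return links


def link_tracks(
    spots: list[Spot],
    params: LinkingParams = LinkingParams(),
    pixel_size: float = 0.106,
) -> list[Track]:
    """Link detected spots into trajectories (independently per cell).

    Tracks shorter than ``min_track_len`` are discarded; tracks shorter
    than ``min_analysis_len`` are kept but flagged ``analysis_ok=False``.
    """
    by_cell: dict[int, list[Spot]] = {}
    for s in spots:
        by_cell.setdefault(s.cell_id, []).append(s)
    all_tracks: list[Track] = []
    next_id = 0
    for cell_id in sorted(by_cell):
        cspots = by_cell[cell_id]
        frames = sorted({s.frame for s in cspots})
        by_frame = {f: [s for s in cspots if s.frame == f] for f in frames}
        active: list[_Active] = []
        done: list[_Active] = []
        lo, hi = params.search_radius_bounds
        no_link = (hi * pixel_size) ** 2 * 1.0001
        for f in range(frames[0], frames[-1] + 1):
            spot_list = by_frame.get(f, [])
            # retire tracks too old to link even across a gap
            still = []
            for tr in active:
                if f - tr.last.frame > params.max_gap + 1:
                    done.append(tr)
                else:
                    still.append(tr)
            active = still
            if not spot_list:
                continue
            if active:
                costs = np.full((len(active), len(spot_list)), 1e12)
                for i, tr in enumerate(active):
                    lag = f - tr.last.frame
                    r = tr.radius_um(lag, params, pixel_size)
                    for j, s in enumerate(spot_list):
                        d2 = (s.x - tr.last.x) ** 2 + (s.y - tr.last.y) ** 2
                        if d2 <= r * r:
                            costs[i, j] = d2
                links = _assign(active, spot_list, costs, no_link)
            else:
                links = []
            linked_spots = set()
            for ti, si in links:
                active[ti].add(spot_list[si])
                linked_spots.add(si)
            for si, s in enumerate(spot_list):
                if si not in linked_spots:
                    active.append(_Active(s))
        done.extend(active)
        for tr in done:
            if len(tr.spots) < params.min_track_len:
                continue
            sp = tr.spots
            all_tracks.append(
                Track(
                    track_id=next_id,
                    cell_id=cell_id,
                    frames=np.array([s.frame for s in sp]),
                    x=np.array([s.x for s in sp]),
                    y=np.array([s.y for s in sp]),
                    psf_width=np.array([s.psf_width for s in sp]),
                    amplitude=np.array([s.amplitude for s in sp]),
                    background=np.array([s.background for s in sp]),
                    analysis_ok=len(sp) >= params.min_analysis_len,
                )
            )
            next_id += 1
    return all_tracks
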