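"""Fixed-cell calibrations.

Chemically fixed cells immobilize every labeled molecule, providing an
all-static reference from which three gates used throughout the analysis are
derived: the lateral localization precision (σ_x, σ_y and their quadrature
sum σ_xy), the long-exposure PSF-width window that selects static molecules
(mean ± 2 SD of a Gaussian fit to fixed-cell widths), and the D* threshold
below which a molecule is called static (mean + 2 SD of the fixed-cell D*
distribution).  A bead-based channel-offset check quantifies chromatic
registration between the two color channels.

Gaussian fits are least squares to a Freedman–Diaconis histogram of the
central peak, with iterative |z| > 3 trimming to shed the small mobile-
molecule tail seen in fixed-cell data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .diffusion import apparent_d_all
from .tracks import Track

__all__ = [
    "PrecisionResult",
    "PsfGate",
    "DstarThreshold",
    "fit_gaussian_peak",
    "localization_precision",
    "psf_width_window",
    "dstar_threshold",
    "channel_offset",
]

log = logging.getLogger(__name__)


@dataclass
class PrecisionResult:
    """Localization precision per axis and in quadrature, nm."""

    sigma_x: float
    sigma_y: float
    n_localizations: int

    @property
    def sigma_xy(self) -> float:
        return math.hypot(self.sigma_x, self.sigma_y)


@dataclass
class PsfGate:
    """Static-molecule PSF-width window (px): gauss_mean ± 2·gauss_sd."""

    gauss_mean: float
    gauss_sd: float
    degenerate: bool = False

    @property
    def w_lo(self) -> float:
        return self.gauss_mean - 2.0 * self.gauss_sd

    @property
    def w_hi(self) -> float:
        return self.gauss_mean + 2.0 * self.gauss_sd

    def window_nm(self, pixel_size_um: float = 0.106) -> tuple[float, float]:
        return (self.w_lo * pixel_size_um * 1e3, self.w_hi * pixel_size_um * 1e3)


@dataclass
class DstarThreshold:
    """Static-molecule D* cutoff (μm²/s): gauss_mean + 2·gauss_sd."""

    gauss_mean: float
    gauss_sd: float

    @property
    def threshold(self) -> float:
        return self.gauss_mean + 2.0 * self.gauss_sd


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def fit_gaussian_peak(
    values: np.ndarray, trim_z: float = 3.0, max_iter: int = 10
) -> tuple[float, float]:
    """(mu, sigma) of the central Gaussian peak of ``values``.

    Least-squares Gaussian fit to a Freedman–Diaconis histogram, iterating
    with values trimmed at |z| > ``trim_z`` until the estimate stabilizes.
    Degenerate inputs (all values equal) return sigma = 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values to fit")
    mu = float(np.median(values))
    sd = float(1.4826 * np.median(np.abs(values - mu)))  # robust start
    if sd == 0:
        sd = float(np.std(values))
    if sd == 0:
        return mu, 0.0
    for _ in range(max_iter):
        sel = values[np.abs(values - mu) <= trim_z * sd]
        if len(sel) < 10:
            break
        q75, q25 = np.percentile(sel, [75, 25])
        h = 2 * (q75 - q25) / len(sel) ** (1 / 3)
        if h <= 0:
            break
        nbins = max(8, int(np.ceil((sel.max() - sel.min()) / h)))
        dens, edges = np.histogram(sel, bins=nbins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            popt, _ = curve_fit(
                _gauss,
                centers,
                dens,
                p0=[dens.max(), mu, sd],
                maxfev=10000,
            )
        except RuntimeError:
            break
        new_mu, new_sd = float(popt[1]), abs(float(popt[2]))
        if abs(new_mu - mu) < 1e-9 and abs(new_sd - sd) < 1e-9:
            mu, sd = new_mu, new_sd
            break
        mu, sd = new_mu, new_sd
    return mu, sd


def localization_precision(fixed_tracks: list[Track]) -> PrecisionResult:
    """Localization precision from fixed-cell trajectories.

    Each trajectory's mean position is subtracted from its localizations;
    the pooled per-axis offsets are fit with Gaussians whose widths are
    σ_x and σ_y (reported in nm), with σ_xy their quadrature sum.  Because
    subtracting a track's own m-point mean shrinks offset variance by
    (1 − 1/m), each track's offsets are rescaled by √(m/(m−1)) so the
    estimate stays unbiased even for short (heavily bleached) tracks.
    """
    offs_x, offs_y = [], []
    for t in fixed_tracks:
        m = len(t)
        if m < 2:
            continue
        corr = math.sqrt(m / (m - 1))
        offs_x.append((t.x - t.x.mean()) * corr)
        offs_y.append((t.y - t.y.mean()) * corr)
    if not offs_x:
        raise ValueError("need at least one track with >= 2 localizations")
    ox = np.concatenate(offs_x)
    oy = np.concatenate(offs_y)
    _, sx = fit_gaussian_peak(ox)
    _, sy = fit_gaussian_peak(oy)
    return PrecisionResult(
        sigma_x=sx * 1e3, sigma_y=sy * 1e3, n_localizations=len(ox)
    )


def psf_width_window(fixed_tracks: list[Track]) -> PsfGate:
    """Static-molecule PSF-width window from fixed-cell tracks.

    Gaussian fit to the distribution of per-track mean PSF widths; the
    window is mean ± 2 SD.  Logs a warning below 50 tracks (unstable fit).
    """
    means = np.array(
        [t.psf_width.mean() for t in fixed_tracks if t.psf_width is not None]
    )
    if len(means) == 0:
        raise ValueError("tracks carry no PSF widths")
    if len(means) < 50:
        log.warning("psf_width_window: only %d tracks; fit may be unstable", len(means))
    if np.ptp(means) == 0:
        return PsfGate(gauss_mean=float(means[0]), gauss_sd=0.0, degenerate=True)
    mu, sd = fit_gaussian_peak(means)
    return PsfGate(gauss_mean=mu, gauss_sd=sd)


def dstar_threshold(fixed_tracks: list[Track], dt: float) -> DstarThreshold:
    """Static-molecule D* cutoff from fixed-cell tracks: Gaussian fit to the
    main peak of the fixed-cell D* distribution, threshold = mean + 2 SD."""
    ests = apparent_d_all(fixed_tracks, dt)
    if not ests:
        raise ValueError("no track with >= 5 localizations")
    vals = np.array([e.d_star for e in ests])
    if np.ptp(vals) == 0:
        return DstarThreshold(gauss_mean=float(vals[0]), gauss_sd=0.0)
    mu, sd = fit_gaussian_peak(vals)
    return DstarThreshold(gauss_mean=mu, gauss_sd=sd)


def channel_offset(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    max_match: float = 0.106,
) -> float:
    """Mean displacement (nm) between matched bead centroids of two channels.

    Centroids in μm; each bead in channel A is matched to the nearest in
    channel B within ``max_match`` (one pixel by default).
    """
    a = np.asarray(centroids_a, dtype=float).reshape(-1, 2)
    b = np.asarray(centroids_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty centroid set")
    tree = cKDTree(b)
    dist, idx = tree.query(a, distance_upper_bound=max_match)
    ok = np.isfinite(dist)
    if not np.any(ok):
        raise ValueError("no centroid matches within one pixel")
    return float(np.mean(dist[ok]) * 1e3)
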