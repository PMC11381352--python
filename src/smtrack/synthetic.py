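"""Ground-truthed synthetic single-molecule imaging data.

This module generates everything the downstream analyses consume — cells,
replisome-like foci, diffusing molecules, and (optionally) rendered EMCCD
movies — with known ground truth, so that detection, tracking, diffusion,
colocalization, and lifetime analysis can each be verified quantitatively.

The default parameters emulate sparse HaloTag labeling of a translesion DNA
polymerase in exponentially growing *B. subtilis*: spherocylindrical cells
(~3.5 × 0.7 μm), one to two replisome foci per cell near the quarter and
three-quarter positions of the long axis, a three-state diffusive mixture
(static / intermediate / fast at ~0.08 / 0.23 / 0.98 μm²/s with fractions
28 / 25 / 47%), Gaussian localization noise (σ_xy ≈ 37 nm at short exposure,
≈ 25 nm at long exposure), single-exponential photobleaching, one-frame
blinking gaps, and an EMCCD camera with a 2065-count offset and 106 nm
pixels.

Molecules keep a single diffusive state for their whole (bleach-limited)
lifetime; state interconversion is not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CellOutline, reflect_step, spherocylinder, uniform_points_in_cell
from .tracks import Track

__all__ = [
    "FociSet",
    "SimulationConfig",
    "GroundTruth",
    "MoleculeTruth",
    "ImageStack",
    "make_cells",
    "place_foci",
    "simulate_tracks",
    "simulate_dataset",
    "simulate_fixed_cells",
    "simulate_mixture_tracks",
    "simulate_binding_durations",
    "render_movie",
]


@dataclass
class FociSet:
    """Replisome-marker foci of one cell."""

    cell_id: int
    centroids: np.ndarray  # (n, 2) μm
    widths: np.ndarray | None = None  # Gaussian sigma, μm
    amplitudes: np.ndarray | None = None  # counts
    backgrounds: np.ndarray | None = None  # counts

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic imaging experiment.

    ``loc_noise_sigma`` may be a scalar (isotropic per-axis σ, μm) or an
    (σx, σy) pair; the lateral precision is their quadrature sum.  The
    default pair reproduces σ_xy = 37.1 nm, the short-exposure calibration.
    """

    frame_interval: float = 0.0147  # s, frame-to-frame clock incl. readout
    integration_time: float = 0.0139  # s
    n_cells: int = 10
    n_molecules: int = 8  # per cell
    n_frames: int = 200
    states: tuple = ((0.28, 0.08), (0.25, 0.23), (0.47, 0.98))  # (fraction, D μm²/s)
    loc_noise_sigma: float | tuple = (0.0265, 0.0260)  # μm per axis
    bleach_lifetime: float = 1.10  # s
    bound_lifetime: float = math.inf  # s; dissociation clock for bound molecules
    blink_prob: float = 0.1
    focus_enrichment: float = 0.5  # P(static molecule seeded near a focus)
    r_seed: float = 0.1  # μm
    pixel_size: float = 0.106  # μm
    camera_offset: float = 2065.0  # counts
    rng_seed: int = 0
    # cell and focus geometry
    cell_length: tuple = (3.48, 0.4)  # (mean, sd) μm
    cell_width: tuple = (0.695, 0.05)
    p_two_foci: float = 0.67  # foci per cell = 1 + Bernoulli(p) -> mean 1.67
    focus_jitter: float = 0.12  # μm, scatter of foci about quarter positions
    # PSF-width emulation (px); per-track base widths are Gaussian
    psf_width_mean: float = 1.424
    psf_width_sd: float = 0.3605
    psf_width_jitter: float = 0.05  # per-localization scatter about the base
    mobile_psf_width_mean: float = 3.2  # long-exposure motion blur
    mobile_psf_width_sd: float = 0.4
    mobile_psf_width_min: float = 2.3
    static_d_max: float = 0.1  # μm²/s; states below this count as static
    # rendering
    render_amplitude: float = 200.0  # photon counts at the Gaussian peak
    render_background: float = 100.0  # photon counts per pixel
    focus_amplitude: float = 600.0
    exposure: str = "short"

    def __post_init__(self) -> None:
        fracs = np.array([s[0] for s in self.states], dtype=float)
        ds = np.array([s[1] for s in self.states], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if np.any(fracs < 0) or np.any(ds < 0):
            raise ValueError("state fractions and D must be non-negative")
        if not (self.frame_interval >= self.integration_time > 0):
            raise ValueError("require frame_interval >= integration_time > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 <= self.blink_prob < 1:
            raise ValueError("blink_prob must be in [0, 1)")

    @property
    def noise_xy(self) -> tuple[float, float]:
        s = self.loc_noise_sigma
        if np.isscalar(s):
            return float(s), float(s)
        return float(s[0]), float(s[1])

    @classmethod
    def long_exposure(cls, **overrides) -> "SimulationConfig":
        """Preset for 250 ms integration (static-molecule selective imaging)."""
        base = dict(
            frame_interval=0.25,
            integration_time=0.25,
            n_frames=60,
            loc_noise_sigma=(0.0174, 0.0181),
            blink_prob=0.0,
            bound_lifetime=1.9,
            exposure="long",
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class MoleculeTruth:
    """Ground truth for one simulated molecule."""

    cell_id: int
    track_id: int
    state_index: int
    d_true: float  # μm²/s
    frames: np.ndarray  # frames with a (possibly blinked-out) true position
    true_x: np.ndarray
    true_y: np.ndarray
    bleach_frame: int  # last frame the fluorophore is on
    seeded_near_focus: bool


@dataclass
class GroundTruth:
    molecules: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.molecules:
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": m.cell_id,
                        "track_id": m.track_id,
                        "state_index": m.state_index,
                        "d_true": m.d_true,
                        "frame": m.frames,
                        "x_true_um": m.true_x,
                        "y_true_um": m.true_y,
                        "bleach_frame": m.bleach_frame,
                        "seeded_near_focus": m.seeded_near_focus,
                    }
                )
            )
        if not rows:
            return pd.DataFrame()
        return pd.concat(rows, ignore_index=True)


@dataclass
class ImageStack:
    """A rendered multi-frame image with its coordinate metadata.

    The continuous position of the center of pixel (row i, col j) is
    ``origin + ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.
    """

    data: np.ndarray  # (T, H, W)
    pixel_size: float  # μm
    origin: tuple = (0.0, 0.0)  # μm position of the (0, 0) pixel corner

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def xy_to_colrow(self, x, y):
        col = (np.asarray(x) - self.origin[0]) / self.pixel_size - 0.5
        row = (np.asarray(y) - self.origin[1]) / self.pixel_size - 0.5
        return col, row

    def colrow_to_xy(self, col, row):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.pixel_size
        return x, y


def make_cells(
    n: int,
    length_dist: tuple = (3.48, 0.4),
    width_dist: tuple = (0.695, 0.05),
    seed: int = 0,
    angle: float = 0.0,
    n_arc: int = 24,
    spacing: float = 1.0,
) -> list[CellOutline]:
    """Generate ``n`` spherocylindrical cells laid out on a grid.

    Lengths and widths are Gaussian with the given (mean, sd); draws are
    clipped so every cell remains a valid rod (length >= 1.05 × width).
    Cells are axis-aligned by default (``angle`` rotates all of them) and
    placed with positive coordinates so they can be rendered directly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_dist[0] <= 0 or width_dist[0] <= 0:
        raise ValueError("cell dimension means must be positive")
    rng = np.random.default_rng(seed)
    lengths = rng.normal(length_dist[0], length_dist[1], size=n)
    widths = rng.normal(width_dist[0], width_dist[1], size=n)
    widths = np.clip(widths, 0.2, None)
    lengths = np.maximum(lengths, 1.05 * widths)
    pitch_x = float(np.max(lengths)) + spacing
    pitch_y = float(np.max(widths)) + spacing
    ncol = max(1, int(math.ceil(math.sqrt(n))))
    cells = []
    for i in range(n):
        r, c = divmod(i, ncol)
        center = (spacing + pitch_x / 2 + c * pitch_x, spacing + pitch_y / 2 + r * pitch_y)
        cells.append(
            spherocylinder(
                cell_id=i,
                length=float(lengths[i]),
                width=float(widths[i]),
                center=center,
                angle=angle,
                n_arc=n_arc,
            )
        )
    return cells


def place_foci(
    cell: CellOutline,
    n_foci: int | None = None,
    p_two: float = 0.67,
    jitter: float = 0.12,
    seed: int | np.random.Generator = 0,
) -> FociSet:
    """Place replisome-like foci in a cell.

    Foci sit at the quarter and three-quarter positions of the long axis and
    on the short-axis midline, plus isotropic Gaussian jitter; draws landing
    outside the outline are rejection-resampled.  When ``n_foci`` is None the
    count is 1 + Bernoulli(``p_two``), matching a mean of ~1.67 foci per
    cell; a single focus occupies one quarter position chosen at random.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_foci is None:
        n_foci = 1 + int(rng.random() < p_two)
    if n_foci == 0:
        return FociSet(cell_id=cell.cell_id, centroids=np.empty((0, 2)))
    if n_foci == 1:
        fracs = [0.25 if rng.random() < 0.5 else 0.75]
    elif n_foci == 2:
        fracs = [0.25, 0.75]
    else:
        fracs = list((np.arange(n_foci) + 0.5) / n_foci)
    pts = []
    for u in fracs:
        x0, y0 = cell.uv_to_xy(u, 0.5)
        for _ in range(10000):
            p = np.array([x0, y0]) + rng.normal(0.0, jitter, size=2)
            if jitter == 0 or bool(cell.contains_xy(p[0], p[1])):
                pts.append(p)
                break
        else:  # pragma: no cover - jitter >> cell size
            pts.append(np.array([x0, y0]))
    return FociSet(cell_id=cell.cell_id, centroids=np.array(pts))


def _seed_position(
    cell: CellOutline, foci: FociSet | None, r_seed: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Initial position: uniform in the cell, or near a focus if seeded."""
    if foci is not None and len(foci) > 0:
        f = foci.centroids[rng.integers(len(foci))]
        for _ in range(1000):
            r = r_seed * math.sqrt(rng.random())
            th = rng.uniform(0, 2 * math.pi)
            p = f + r * np.array([math.cos(th), math.sin(th)])
            if bool(cell.contains_xy(p[0], p[1])):
                return p, True
    return uniform_points_in_cell(cell, 1, rng)[0], False


def _blink_mask(n: int, blink_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Keep-mask over n frames: interior frames drop with prob blink_prob,
    never two in a row (gaps are at most one frame long)."""
    keep = np.ones(n, dtype=bool)
    for i in range(1, n - 1):
        if keep[i - 1] and rng.random() < blink_prob:
            keep[i] = False
    return keep


def simulate_tracks(
    cell: CellOutline,
    foci: FociSet | None,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    track_id_start: int = 0,
) -> tuple[list[Track], GroundTruth]:
    """Simulate the molecules of one cell.

    Each molecule draws a diffusive state from the configured mixture, starts
    at a random frame, performs reflected 2D Brownian motion inside the cell
    polygon (per-axis step variance 2·D·Δt), bleaches after an
    Exponential(τ_bleach) time, blinks away single interior frames, and is
    observed with additive Gaussian localization noise.  Static molecules
    (D below ``static_d_max``) are seeded within ``r_seed`` of a focus with
    probability ``focus_enrichment``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    fracs = np.array([s[0] for s in cfg.states])
    ds = np.array([s[1] for s in cfg.states])
    sx, sy = cfg.noise_xy
    dt = cfg.frame_interval
    long_mode = cfg.exposure == "long"
    tracks: list[Track] = []
    truths: list[MoleculeTruth] = []
    for m in range(cfg.n_molecules):
        s_idx = int(rng.choice(len(fracs), p=fracs))
        d = float(ds[s_idx])
        seeded = False
        if d <= cfg.static_d_max and rng.random() < cfg.focus_enrichment:
            pos, seeded = _seed_position(cell, foci, cfg.r_seed, rng)
        else:
            pos = uniform_points_in_cell(cell, 1, rng)[0]
        f0 = int(rng.integers(0, cfg.n_frames))
        t_on = rng.exponential(cfg.bleach_lifetime)
        # in long-exposure imaging only bound molecules are resolvable, and
        # dissociation ends the trajectory just as bleaching does
        if (
            long_mode
            and d <= cfg.static_d_max
            and math.isfinite(cfg.bound_lifetime)
        ):
            t_on = min(t_on, rng.exponential(cfg.bound_lifetime))
        n_on = max(1, math.ceil(t_on / dt))
        n_obs = min(n_on, cfg.n_frames - f0)
        frames = np.arange(f0, f0 + n_obs)
        xs = np.empty(n_obs)
        ys = np.empty(n_obs)
        xs[0], ys[0] = pos
        sig = math.sqrt(2.0 * d * dt)
        for i in range(1, n_obs):
            step = rng.normal(0.0, sig, size=2) if sig > 0 else np.zeros(2)
            pos = reflect_step(cell, pos, pos + step)
            xs[i], ys[i] = pos
        keep = _blink_mask(n_obs, cfg.blink_prob, rng)
        obs_x = xs + rng.normal(0.0, sx, size=n_obs) if sx > 0 else xs.copy()
        obs_y = ys + rng.normal(0.0, sy, size=n_obs) if sy > 0 else ys.copy()
        # PSF widths: static-like unless this is long-exposure imaging of a
        # mobile molecule, whose blurred spot is broader than the gate
        if long_mode and d > cfg.static_d_max:
            base = max(
                cfg.mobile_psf_width_min,
                rng.normal(cfg.mobile_psf_width_mean, cfg.mobile_psf_width_sd),
            )
        else:
            base = rng.normal(cfg.psf_width_mean, cfg.psf_width_sd)
        widths = np.clip(base + rng.normal(0, cfg.psf_width_jitter, n_obs), 0.3, None)
        tid = track_id_start + m
        tracks.append(
            Track(
                track_id=tid,
                cell_id=cell.cell_id,
                frames=frames[keep],
                x=obs_x[keep],
                y=obs_y[keep],
                psf_width=widths[keep],
                amplitude=np.full(keep.sum(), cfg.render_amplitude),
                background=np.full(keep.sum(), cfg.render_background + cfg.camera_offset),
            )
        )
        truths.append(
            MoleculeTruth(
                cell_id=cell.cell_id,
                track_id=tid,
                state_index=s_idx,
                d_true=d,
                frames=frames,
                true_x=xs,
                true_y=ys,
                bleach_frame=int(frames[-1]),
                seeded_near_focus=seeded,
            )
        )
    return tracks, GroundTruth(truths)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[CellOutline], list[FociSet], list[Track], GroundTruth]:
    """Fan out a whole experiment: cells, foci, and tracks for every cell.

    A single master seed drives everything; per-cell generators are spawned
    from a SeedSequence so cells are independent and reproducible.
    """
    ss = np.random.SeedSequence(cfg.rng_seed)
    mol_seeds = ss.spawn(cfg.n_cells)
    cells = make_cells(
        cfg.n_cells, cfg.cell_length, cfg.cell_width, seed=int(cfg.rng_seed) & 0x7FFFFFFF
    )
    foci_sets = []
    all_tracks: list[Track] = []
    truths = []
    tid = 0
    for cell, mseed in zip(cells, mol_seeds):
        rng = np.random.default_rng(mseed)
        foci = place_foci(
            cell, None, p_two=cfg.p_two_foci, jitter=cfg.focus_jitter, seed=rng
        )
        foci_sets.append(foci)
        tr, gt = simulate_tracks(cell, foci, cfg, rng=rng, track_id_start=tid)
        tid += cfg.n_molecules
        all_tracks.extend(tr)
        truths.extend(gt.molecules)
    return cells, foci_sets, all_tracks, GroundTruth(truths)


def simulate_fixed_cells(
    cfg: SimulationConfig,
) -> tuple[list[CellOutline], list[Track], GroundTruth]:
    """All-static control (chemically fixed cells): every molecule has D = 0.

    Used to calibrate localization precision, the PSF-width gate, the static
    D* threshold, and the photobleaching lifetime.
    """
    fixed_cfg = replace(
        cfg, states=((1.0, 0.0),), focus_enrichment=0.0, bound_lifetime=math.inf
    )
    cells, _, tracks, gt = simulate_dataset(fixed_cfg)
    return cells, tracks, gt


def simulate_mixture_tracks(
    n_tracks: int,
    states: tuple = ((0.28, 0.08), (0.25, 0.23), (0.47, 0.98)),
    n_steps: int = 4,
    dt: float = 0.0147,
    loc_sigma: float | tuple = 0.0,
    seed: int = 0,
) -> tuple[list[Track], np.ndarray]:
    """Vectorized free (unconfined) Brownian mixture - the parameter-recovery
    oracle for the diffusion fits, where confinement would bias apparent D.

    Returns (tracks, true state index per track).
    """
    rng = np.random.default_rng(seed)
    fracs = np.array([s[0] for s in states])
    ds = np.array([s[1] for s in states])
    labels = rng.choice(len(fracs), p=fracs, size=n_tracks)
    sig = np.sqrt(2.0 * ds[labels] * dt)[:, None]
    steps_x = rng.normal(0.0, 1.0, size=(n_tracks, n_steps)) * sig
    steps_y = rng.normal(0.0, 1.0, size=(n_tracks, n_steps)) * sig
    x = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(steps_x, axis=1)], axis=1)
    y = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(steps_y, axis=1)], axis=1)
    if np.isscalar(loc_sigma):
        sxy = (float(loc_sigma), float(loc_sigma))
    else:
        sxy = (float(loc_sigma[0]), float(loc_sigma[1]))
    if sxy[0] > 0 or sxy[1] > 0:
        x = x + rng.normal(0.0, sxy[0], size=x.shape)
        y = y + rng.normal(0.0, sxy[1], size=y.shape)
    frames = np.arange(n_steps + 1)
    tracks = [
        Track(track_id=i, cell_id=0, frames=frames, x=x[i], y=y[i])
        for i in range(n_tracks)
    ]
    return tracks, labels


def simulate_binding_durations(
    n: int,
    tau_bound: float,
    tau_bleach: float,
    frame_time: float,
    seed: int = 0,
    min_frames: int | None = None,
) -> np.ndarray:
    """Observed track durations when dissociation (τ_bound) competes with
    photobleaching (τ_bleach): the on-time is the minimum of two
    exponentials (rates add), quantized to whole frames.

    With ``min_frames`` set, sampling continues until ``n`` durations at or
    above the exclusion threshold are collected (the durations entering a
    left-truncated fit).
    """
    rng = np.random.default_rng(seed)
    rate = 1.0 / tau_bound + 1.0 / tau_bleach
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        t = rng.exponential(1.0 / rate, size=max(n - got, 16) * 2)
        dur = np.ceil(t / frame_time) * frame_time
        dur = np.maximum(dur, frame_time)
        if min_frames is not None:
            dur = dur[dur >= min_frames * frame_time - 1e-12]
        out.append(dur[: n - got])
        got += len(out[-1])
    return np.concatenate(out)[:n]


def _render_gaussian(img: np.ndarray, col: float, row: float, sigma_px: float, amp: float):
    """Add a symmetric 2D Gaussian (peak ``amp``) onto ``img`` in place."""
    h, w = img.shape
    r = max(3, int(math.ceil(4 * sigma_px)))
    i0, i1 = int(round(row)) - r, int(round(row)) + r + 1
    j0, j1 = int(round(col)) - r, int(round(col)) + r + 1
    i0c, i1c = max(i0, 0), min(i1, h)
    j0c, j1c = max(j0, 0), min(j1, w)
    if i0c >= i1c or j0c >= j1c:
        return
    ii = np.arange(i0c, i1c)
    jj = np.arange(j0c, j1c)
    gy = np.exp(-((ii - row) ** 2) / (2 * sigma_px**2))
    gx = np.exp(-((jj - col) ** 2) / (2 * sigma_px**2))
    img[i0c:i1c, j0c:j1c] += amp * gy[:, None] * gx[None, :]


def render_movie(
    cells: list[CellOutline],
    foci: list[FociSet] | None,
    tracks: list[Track] | None,
    cfg: SimulationConfig,
    n_frames: int | None = None,
    margin: float = 1.0,
    poisson_noise: bool = True,
    seed: int | None = None,
) -> ImageStack:
    """Render a 16-bit EMCCD-like movie of the simulated experiment.

    Every visible localization becomes a symmetric 2D Gaussian with its
    track's PSF width; foci are rendered in every frame.  Pixel values are
    ``camera_offset + Poisson(background + signal)``.
    """
    if not cells:
        raise ValueError("need at least one cell to define the field of view")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    bounds = np.array([c.polygon.bounds for c in cells])
    minx, miny = bounds[:, 0].min() - margin, bounds[:, 1].min() - margin
    maxx, maxy = bounds[:, 2].max() + margin, bounds[:, 3].max() + margin
    px = cfg.pixel_size
    w = int(math.ceil((maxx - minx) / px))
    h = int(math.ceil((maxy - miny) / px))
    origin = (minx, miny)
    if n_frames is None:
        n_frames = cfg.n_frames
    # index localizations by frame
    by_frame: dict[int, list] = {}
    for t in tracks or []:
        for k in range(len(t)):
            f = int(t.frames[k])
            if f < n_frames:
                wpx = t.psf_width[k] if t.psf_width is not None else cfg.psf_width_mean
                amp = t.amplitude[k] if t.amplitude is not None else cfg.render_amplitude
                by_frame.setdefault(f, []).append((t.x[k], t.y[k], wpx, amp))
    focus_pts = []
    for fs in foci or []:
        for i, (fx, fy) in enumerate(fs.centroids):
            wum = fs.widths[i] if fs.widths is not None else 1.4 * px
            amp = fs.amplitudes[i] if fs.amplitudes is not None else cfg.focus_amplitude
            focus_pts.append((fx, fy, wum / px, amp))
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    for f in range(n_frames):
        expected = np.full((h, w), cfg.render_background, dtype=float)
        for (x, y, wpx, amp) in focus_pts + by_frame.get(f, []):
            col = (x - origin[0]) / px - 0.5
            row = (y - origin[1]) / px - 0.5
            _render_gaussian(expected, col, row, wpx, amp)
        if poisson_noise:
            img = rng.poisson(expected).astype(float)
        else:
            img = expected
        stack[f] = np.clip(img + cfg.camera_offset, 0, 65535).astype(np.uint16)
    return ImageStack(data=stack, pixel_size=px, origin=origin)
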