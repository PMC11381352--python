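"""Apparent diffusion coefficients and mixture models.

Two complementary quantifications of single-molecule mobility:

* **MSD / D\*** — the apparent 2D diffusion coefficient of a short
  trajectory, ``D* = MSD / (4 Δt)`` with the MSD averaged over consecutive
  single-frame displacements.  For trajectories truncated to exactly four
  steps, the D* values of a single species with true coefficient D follow a
  gamma density ``(4/D)^4 / 6 · x³ · exp(-4x/D)`` (shape 4, rate 4/D), and a
  mixture of three such terms is fit to the observed D* histogram with the
  amplitude constraint A1 + A2 + A3 = 1.  D* folds localization noise into
  the estimate: for an immobile molecule with per-axis noise σ,
  E[D*] = σ²/Δt, which is why a fixed-cell calibration sets the static
  cutoff (0.14 μm²/s here) rather than zero.

* **Jump-length kinetic model** — empirical jump-length CDFs at lags of one
  to four frames are fit with a two-state (bound + free) model in which each
  state contributes a Rayleigh-type CDF with effective variance
  ``4 (D k Δt + σ_loc²)``, and the free state's weight decays with lag by an
  axial-retention factor P_stay (molecules diffusing out of the detection
  slab of depth dZ are lost).  P_stay is tabulated by 1D out-of-slab Monte
  Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tracks import Track

__all__ = [
    "DiffusionEstimate",
    "ThreeSpeciesFit",
    "JumpLengthFit",
    "track_msd",
    "apparent_d",
    "three_species_pdf",
    "fit_three_species",
    "classify_static",
    "jump_length_cdfs",
    "p_stay",
    "fit_two_state",
    "STATIC_DSTAR_CUTOFF",
]

#: Static/mobile D* cutoff (μm²/s) from the fixed-cell calibration.
STATIC_DSTAR_CUTOFF = 0.14


@dataclass
class DiffusionEstimate:
    track_id: int
    d_star: float  # μm²/s
    n_steps: int  # consecutive-frame displacement pairs used
    dt: float  # s


@dataclass
class ThreeSpeciesFit:
    """Amplitudes and diffusion coefficients of the three-species D* mixture,
    in canonical order D1 <= D2 <= D3, with A1 + A2 + A3 = 1."""

    a: tuple  # (A1, A2, A3)
    d: tuple  # (D1, D2, D3) μm²/s
    residual_norm: float = math.nan
    n_tracks: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.a) - 1.0) > 1e-6:
            raise ValueError("amplitudes must sum to 1")
        if any(x <= 0 for x in self.d):
            raise ValueError("diffusion coefficients must be positive")


@dataclass
class JumpLengthFit:
    f_bound: float
    d_bound: float  # μm²/s
    d_free: float  # μm²/s
    loc_error: float  # μm
    dz: float  # μm
    time_gap: float  # s
    n_timepoints: int
    n_jumps: int
    residual_norm: float
    boundary_solution: bool = False


def track_msd(track: Track) -> float:
    """Mean squared single-frame displacement (μm²).

    Averages (x_{i+1}-x_i)² + (y_{i+1}-y_i)² over consecutive-frame pairs;
    displacements spanning a blinking gap are excluded from both the sum and
    the divisor, so the MSD always refers to one frame interval.
    """
    if len(track) < 2:
        raise ValueError("MSD requires at least two localizations")
    consec = np.diff(track.frames) == 1
    if not np.any(consec):
        raise ValueError("track has no consecutive-frame displacement")
    dx = np.diff(track.x)[consec]
    dy = np.diff(track.y)[consec]
    return float(np.mean(dx**2 + dy**2))


def apparent_d(track: Track, dt: float, truncate: int = 5) -> DiffusionEstimate:
    """Apparent diffusion coefficient D* = MSD / (4 Δt) of one trajectory.

    Requires at least five localizations; longer trajectories are truncated
    to their first five localizations (four steps) so that all D* values are
    comparable and follow the exactly-four-step mixture density.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(track) < truncate:
        raise ValueError(f"track needs >= {truncate} localizations for D*")
    sub = Track(
        track_id=track.track_id,
        cell_id=track.cell_id,
        frames=track.frames[:truncate],
        x=track.x[:truncate],
        y=track.y[:truncate],
    )
    msd = track_msd(sub)
    n_steps = int(np.sum(np.diff(sub.frames) == 1))
    return DiffusionEstimate(
        track_id=track.track_id, d_star=msd / (4.0 * dt), n_steps=n_steps, dt=dt
    )


def apparent_d_all(
    tracks: list[Track], dt: float, min_len: int = 5
) -> list[DiffusionEstimate]:
    """D* for every track with at least ``min_len`` localizations."""
    out = []
    for t in tracks:
        if len(t) >= min_len:
            try:
                out.append(apparent_d(t, dt))
            except ValueError:
                continue
    return out


def three_species_pdf(x, a1, a2, a3, d1, d2, d3):
    """Probability density of D* for a three-species mixture of four-step
    trajectories: each species n contributes A_n (4/D_n)^4 / 6 · x³ e^(-4x/D_n).
    """
    if min(d1, d2, d3) <= 0:
        raise ValueError("diffusion coefficients must be positive")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for a, d in ((a1, d1), (a2, d2), (a3, d3)):
        out = out + a * (4.0 / d) ** 4 / 6.0 * x**3 * np.exp(-4.0 * x / d)
    return out


def _hist_density(values, bin_width, r_max):
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    dens, _ = np.histogram(np.clip(values, 0, r_max - 1e-12), bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def fit_three_species(
    d_stars,
    init: ThreeSpeciesFit | None = None,
    bin_width: float = 0.05,
    r_max: float = 3.0,
) -> ThreeSpeciesFit:
    """Least-squares fit of the three-species density to the D* histogram.

    The normalization constraint is enforced by parameterizing
    A3 = 1 - A1 - A2 with box constraints on A1, A2; several starting points
    are tried and the best residual kept; the result is reported with
    species sorted by D.
    """
    d_stars = np.asarray(d_stars, dtype=float)
    if np.any(d_stars < 0):
        raise ValueError("D* values must be non-negative")
    centers, dens = _hist_density(d_stars, bin_width, r_max)

    def resid(p):
        a1, a2, d1, d2, d3 = p
        a3 = 1.0 - a1 - a2
        pen = max(0.0, -a3) * 100.0
        model = three_species_pdf(centers, a1, a2, max(a3, 0.0), d1, d2, d3)
        return np.append(model - dens, pen)

    inits = []
    if init is not None:
        inits.append([init.a[0], init.a[1], *init.d])
    q = np.quantile(d_stars, [0.15, 0.5, 0.85]) + 1e-3
    inits.append([0.33, 0.33, q[0], q[1], q[2]])
    inits.append([0.28, 0.25, 0.08, 0.23, 0.98])
    inits.append([0.2, 0.4, 0.05, 0.4, 1.5])
    lb = [0.0, 0.0, 1e-4, 1e-4, 1e-4]
    ub = [1.0, 1.0, 10.0, 10.0, 10.0]
    best = None
    for x0 in inits:
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("three-species fit failed to converge from all starts")
    a1, a2, d1, d2, d3 = best.x
    a3 = max(0.0, 1.0 - a1 - a2)
    tot = a1 + a2 + a3
    amps = np.array([a1, a2, a3]) / tot
    ds = np.array([d1, d2, d3])
    order = np.argsort(ds)
    return ThreeSpeciesFit(
        a=tuple(float(v) for v in amps[order]),
        d=tuple(float(v) for v in ds[order]),
        residual_norm=float(np.sqrt(2 * best.cost)),
        n_tracks=len(d_stars),
    )


def classify_static(
    estimates: list[DiffusionEstimate], threshold: float = STATIC_DSTAR_CUTOFF
) -> np.ndarray:
    """Label each estimate 'static' (D* strictly below the threshold) or
    'mobile'."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.array(
        ["static" if e.d_star < threshold else "mobile" for e in estimates]
    )


def jump_length_cdfs(
    tracks: list[Track],
    n_timepoints: int = 4,
    jumps_to_consider: int = 4,
    max_jump: float = 5.05,
    bin_width: float = 0.01,
) -> dict:
    """Empirical jump-length CDFs for lags of 1..n_timepoints frames.

    Trajectories of any length contribute; for each lag at most
    ``jumps_to_consider`` jumps are taken per track (from its start) and
    jumps at or beyond ``max_jump`` are excluded.  Returns a dict
    ``lag -> (r_grid, cdf, n_jumps)`` on a common grid of ``bin_width``
    spacing.
    """
    grid = np.arange(bin_width, max_jump + bin_width / 2, bin_width)
    jumps: dict[int, list] = {k: [] for k in range(1, n_timepoints + 1)}
    for t in tracks:
        for k in range(1, n_timepoints + 1):
            taken = 0
            # pair localizations exactly k frames apart (gaps produce lag-2
            # pairs naturally because the missing frame is absent)
            frame_index = {int(f): i for i, f in enumerate(t.frames)}
            for f, i in frame_index.items():
                if taken >= jumps_to_consider:
                    break
                j = frame_index.get(f + k)
                if j is None:
                    continue
                r = math.hypot(t.x[j] - t.x[i], t.y[j] - t.y[i])
                if r < max_jump:
                    jumps[k].append(r)
                    taken += 1
    out = {}
    for k, vals in jumps.items():
        vals = np.asarray(vals)
        if len(vals):
            cdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
        else:
            cdf = np.zeros_like(grid)
        out[k] = (grid, cdf, len(vals))
    return out


def p_stay(
    d: float,
    lag_time: float,
    dz: float = 0.7,
    n_particles: int = 20000,
    n_substeps: int = 10,
    seed: int = 12345,
) -> float:
    """Probability that a molecule with axial diffusion coefficient ``d``
    starting uniformly in a slab of depth ``dz`` has not left it after
    ``lag_time`` (absorbing exits, Monte-Carlo with substepping)."""
    if not np.isfinite(dz):
        return 1.0
    if d <= 0 or lag_time <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    half = dz / 2.0
    z = rng.uniform(-half, half, size=n_particles)
    alive = np.ones(n_particles, dtype=bool)
    sig = math.sqrt(2.0 * d * lag_time / n_substeps)
    for _ in range(n_substeps):
        z = z + rng.normal(0.0, sig, size=n_particles)
        alive &= np.abs(z) <= half
        z[~alive] = np.inf  # absorbed
        z[alive] = z[alive]
    return float(np.mean(alive))


class _PStayTable:
    """Interpolated P_stay over a log-spaced D grid, one curve per lag."""

    def __init__(self, lags_s, dz, n_d=25, d_range=(1e-4, 30.0), seed=12345):
        self.lags_s = list(lags_s)
        self.dz = dz
        self.d_grid = np.geomspace(d_range[0], d_range[1], n_d)
        if np.isfinite(dz):
            self.tables = [
                np.array([p_stay(d, lag, dz, seed=seed) for d in self.d_grid])
                for lag in self.lags_s
            ]
        else:
            self.tables = [np.ones_like(self.d_grid) for _ in self.lags_s]

    def __call__(self, lag_index: int, d: float) -> float:
        d = min(max(d, self.d_grid[0]), self.d_grid[-1])
        return float(
            np.interp(math.log(d), np.log(self.d_grid), self.tables[lag_index])
        )


def _two_state_cdf(r, k_dt, f_bound, d_bound, d_free, loc_error, zcorr):
    """Model CDF of jump lengths at one lag.

    Each state is a 2D Gaussian displacement with effective variance
    4 (D k Δt + σ²); the free state's weight is reduced by the axial
    retention factor ``zcorr`` and the mixture renormalized.
    """
    s2b = 4.0 * (d_bound * k_dt + loc_error**2)
    s2f = 4.0 * (d_free * k_dt + loc_error**2)
    wb = f_bound
    wf = (1.0 - f_bound) * zcorr
    tot = wb + wf
    cb = 1.0 - np.exp(-(r**2) / s2b)
    cf = 1.0 - np.exp(-(r**2) / s2f)
    return (wb * cb + wf * cf) / tot


def fit_two_state(
    cdfs: dict,
    loc_error: float = 0.037,
    dz: float = 0.7,
    time_gap: float = 0.0147,
    bounds: tuple = ((1e-4, 0.1), (0.5, 25.0)),
    fit_iterations: int = 3,
    seed: int = 12345,
) -> JumpLengthFit:
    """Fit the two-state (bound + free) jump-length model to empirical CDFs.

    ``bounds`` gives (D_bound range, D_free range) in μm²/s.  The optimizer
    restarts from ``fit_iterations`` spread initializations and keeps the
    best residual.  Solutions pinned at a box bound are flagged.
    """
    lags = sorted(cdfs.keys())
    lag_times = [k * time_gap for k in lags]
    table = _PStayTable(lag_times, dz, seed=seed)
    (db_lo, db_hi), (df_lo, df_hi) = bounds

    # subsample the fine CDF grid for speed; the CDF is smooth
    data = []
    for k in lags:
        grid, cdf, n = cdfs[k]
        step = max(1, len(grid) // 200)
        data.append((k, grid[::step], cdf[::step], n))

    def resid(p):
        f, db, df = p
        out = []
        for idx, (k, grid, cdf, n) in enumerate(data):
            if n == 0:
                continue
            z = table(idx, df)
            model = _two_state_cdf(grid, k * time_gap, f, db, df, loc_error, z)
            out.append(model - cdf)
        return np.concatenate(out)

    inits = [
        [0.3, math.sqrt(db_lo * db_hi), math.sqrt(df_lo * df_hi)],
        [0.6, db_hi * 0.5, df_lo * 2.0],
        [0.1, db_lo * 5.0, df_hi * 0.2],
    ]
    lb = [0.0, db_lo, df_lo]
    ub = [1.0, db_hi, df_hi]
    best = None
    for x0 in inits[:max(1, fit_iterations)]:
        x0 = np.clip(x0, lb, ub)
        res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=2000)
        if best is None or res.cost < best.cost:
            best = res
    f, db, df = best.x
    on_bound = bool(
        np.isclose(db, db_lo) or np.isclose(db, db_hi)
        or np.isclose(df, df_lo) or np.isclose(df, df_hi)
    )
    return JumpLengthFit(
        f_bound=float(f),
        d_bound=float(db),
        d_free=float(df),
        loc_error=loc_error,
        dz=dz,
        time_gap=time_gap,
        n_timepoints=len(lags),
        n_jumps=0 if not data else max(d[3] for d in data),
        residual_norm=float(np.sqrt(2 * best.cost)),
        boundary_solution=on_bound,
    )
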