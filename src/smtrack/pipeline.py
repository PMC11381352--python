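"""End-to-end analysis pipeline and group statistics.

``run_pipeline`` ties the stages together on simulated (or loaded) data:
synthesis → (optional) rendering + detection + linking → fixed-cell
calibration → diffusion mixture and jump-length fits → normalized-cell
localization → radial distribution colocalization → long-exposure binding
lifetimes.  Every parameter actually used is echoed into the summary, and
all randomness derives from the single master seed, so a run is
reproducible from its summary file alone.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import stats as _stats

from . import __version__
from . import calibration as cal
from . import cellcoords as cc
from . import colocalization as coloc
from . import detect as det
from . import diffusion as diff
from . import io as sio
from . import lifetimes as lt
from . import synthetic as syn

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "compare_groups"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": None,  # directory for CSV/JSON outputs; None = nothing written
    "exposure": "both",  # short | long | both
    "n_cells": 30,
    "n_molecules": 8,
    "n_frames": 300,
    "states": [[0.28, 0.08], [0.25, 0.23], [0.47, 0.98]],
    "focus_enrichment": 0.5,
    "r_seed": 0.1,
    "bleach_lifetime": 1.10,
    "frame_interval_short": 0.0147,
    "frame_interval_long": 0.25,
    "n_frames_long": 120,
    "n_molecules_long": 50,
    "bound_lifetime": 1.9,
    "n_cells_fixed": 30,
    "dstar_threshold": 0.14,
    "min_frames_lifetime": 5,
    "gr": {"bin_width": 0.025, "r_max": 1.0, "n_repeats": 100},
    "spoton": {
        "loc_error": 0.037,
        "dz": 0.7,
        "n_timepoints": 4,
        "jumps_to_consider": 4,
        "max_jump": 5.05,
        "bin_width": 0.01,
        "d_bound_range": [0.0001, 0.1],
        "d_free_range": [0.5, 25.0],
        "fit_iterations": 3,
    },
    "render_detect": {"enabled": True, "n_cells": 4, "n_frames": 12},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for k, v in (override or {}).items():
        if k not in defaults:
            raise ValueError(f"unknown config key: {path + k}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge(defaults[k], v, path + k + ".")
        else:
            out[k] = copy.deepcopy(v)
    return out


def compare_groups(values_a, values_b) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Returns the statistic, the two-sided p-value, and significance at 0.05.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = _stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < 0.05),
        "n_a": len(a),
        "n_b": len(b),
    }


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: dict | None = None) -> dict:
    """Run the demo pipeline on synthetic data and return the summary.

    ``config`` overrides keys of :data:`DEFAULT_CONFIG` (unknown keys are
    rejected).  With ``out_dir`` set, tracks/cells/foci and the summary
    JSON are written there; partial outputs survive a failing stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg, "seed": seed, "version": __version__}
    states = tuple((float(a), float(d)) for a, d in cfg["states"])

    @_stage("simulate")
    def do_simulate():
        sim = syn.SimulationConfig(
            frame_interval=cfg["frame_interval_short"],
            n_cells=cfg["n_cells"],
            n_molecules=cfg["n_molecules"],
            n_frames=cfg["n_frames"],
            states=states,
            bleach_lifetime=cfg["bleach_lifetime"],
            focus_enrichment=cfg["focus_enrichment"],
            r_seed=cfg["r_seed"],
            rng_seed=seed,
        )
        cells, foci, tracks, gt = syn.simulate_dataset(sim)
        if out_dir:
            sio.write_cells(cells, out_dir / "cells.json")
            sio.write_foci(foci, out_dir / "foci.json")
            sio.write_tracks(tracks, out_dir / "tracks_short.csv")
            gt.to_frame().to_csv(out_dir / "ground_truth.csv", index=False)
        summary["simulate"] = {
            "n_cells": len(cells),
            "n_tracks": len(tracks),
            "frame_interval_s": sim.frame_interval,
        }
        return sim, cells, foci, tracks

    sim, cells, foci, tracks = do_simulate()
    foci_by_cell = {f.cell_id: f for f in foci}

    @_stage("detect")
    def do_detect():
        rd = cfg["render_detect"]
        sub_cells = cells[: rd["n_cells"]]
        sub_tracks = [t for t in tracks if t.cell_id < rd["n_cells"]]
        movie = syn.render_movie(
            sub_cells, None, sub_tracks, sim, n_frames=rd["n_frames"], seed=seed + 1
        )
        spots = det.detect_stack(movie, sub_cells, det.DetectionParams(alpha=1e-5))
        linked = det.link_tracks(spots, det.LinkingParams(), movie.pixel_size)
        summary["detect"] = {
            "n_spots": len(spots),
            "n_tracks_linked": len(linked),
            "alpha": 1e-5,
        }

    if cfg["render_detect"]["enabled"]:
        do_detect()

    @_stage("calibrate")
    def do_calibrate():
        fix_cfg = replace(
            sim, n_cells=cfg["n_cells_fixed"], rng_seed=seed + 101, n_frames=120
        )
        _, fixed_tracks, _ = syn.simulate_fixed_cells(fix_cfg)
        prec = cal.localization_precision(fixed_tracks)
        thr = cal.dstar_threshold(
            [t for t in fixed_tracks if len(t) >= 5], sim.frame_interval
        )
        summary["calibration"] = {
            "sigma_x_nm": prec.sigma_x,
            "sigma_y_nm": prec.sigma_y,
            "sigma_xy_nm": prec.sigma_xy,
            "n_localizations": prec.n_localizations,
            "dstar_threshold_um2_s": thr.threshold,
        }
        return fixed_tracks

    fixed_tracks = do_calibrate()

    @_stage("diffusion")
    def do_diffusion():
        ests = diff.apparent_d_all(tracks, sim.frame_interval)
        d_stars = [e.d_star for e in ests if e.n_steps == 4]
        fit3 = diff.fit_three_species(d_stars)
        labels = diff.classify_static(ests, cfg["dstar_threshold"])
        sp = cfg["spoton"]
        cdfs = diff.jump_length_cdfs(
            tracks,
            n_timepoints=sp["n_timepoints"],
            jumps_to_consider=sp["jumps_to_consider"],
            max_jump=sp["max_jump"],
            bin_width=sp["bin_width"],
        )
        fit2 = diff.fit_two_state(
            cdfs,
            loc_error=sp["loc_error"],
            dz=sp["dz"],
            time_gap=sim.frame_interval,
            bounds=(tuple(sp["d_bound_range"]), tuple(sp["d_free_range"])),
            fit_iterations=sp["fit_iterations"],
        )
        summary["diffusion"] = {
            "n_dstar": len(ests),
            "three_species": {
                "fractions": list(fit3.a),
                "d_um2_s": list(fit3.d),
                "residual_norm": fit3.residual_norm,
            },
            "static_fraction_threshold": float(np.mean(labels == "static")),
            "two_state": {
                "f_bound": fit2.f_bound,
                "d_bound": fit2.d_bound,
                "d_free": fit2.d_free,
                "n_jumps": fit2.n_jumps,
                "boundary_solution": fit2.boundary_solution,
            },
        }

    @_stage("coords")
    def do_coords():
        by_cell = cc.track_mean_positions([t for t in tracks if t.analysis_ok])
        pts = []
        for cell in cells:
            if cell.cell_id in by_cell:
                pts.extend(
                    cc.normalize_coordinates(
                        by_cell[cell.cell_id], cell, source="trajectory-mean"
                    )
                )
        (uc, ud), (vc, vd) = cc.axis_histograms(pts, n_bins=20)
        summary["coords"] = {
            "n_points": len(pts),
            "u_density": ud.tolist(),
            "v_density": vd.tolist(),
        }
        if out_dir:
            np.savetxt(
                out_dir / "normalized_points.csv",
                np.array([[p.cell_id, p.u, p.v] for p in pts]),
                delimiter=",",
                header="cell_id,u,v",
                comments="",
            )

    @_stage("gr")
    def do_gr():
        recs = coloc.trajectory_focus_distances(
            [t for t in tracks if t.analysis_ok], foci_by_cell
        )
        counts: dict[int, int] = {}
        for r in recs:
            counts[r.cell_id] = counts.get(r.cell_id, 0) + 1
        g = coloc.radial_distribution(
            recs,
            cells,
            foci_by_cell,
            counts,
            bin_width=cfg["gr"]["bin_width"],
            r_max=cfg["gr"]["r_max"],
            n_repeats=cfg["gr"]["n_repeats"],
            seed=seed + 201,
        )
        summary["gr"] = {
            "r_um": g.r.tolist(),
            "g": g.g.tolist(),
            "sem": g.sem.tolist(),
            "max_g": float(
                np.nanmax(g.g[g.n_defined >= max(2, g.n_repeats // 2)])
            ),
            "n_trajectories": len(recs),
        }
        if out_dir:
            np.savetxt(
                out_dir / "gr.csv",
                np.column_stack([g.r, g.g, g.sem]),
                delimiter=",",
                header="r_um,g,sem",
                comments="",
            )

    if cfg["exposure"] in ("short", "both"):
        do_diffusion()
        do_coords()
        do_gr()

    @_stage("lifetimes")
    def do_lifetimes():
        long_cfg = syn.SimulationConfig.long_exposure(
            n_cells=cfg["n_cells"],
            n_molecules=cfg["n_molecules_long"],
            n_frames=cfg["n_frames_long"],
            states=states,
            bleach_lifetime=cfg["bleach_lifetime"],
            bound_lifetime=cfg["bound_lifetime"],
            rng_seed=seed + 301,
        )
        _, _, long_tracks, _ = syn.simulate_dataset(long_cfg)
        fix_cfg = replace(long_cfg, rng_seed=seed + 401)
        _, fixed_long, _ = syn.simulate_fixed_cells(fix_cfg)
        gate = cal.psf_width_window(fixed_long)
        static = lt.select_static_long_exposure(long_tracks, gate)
        fit = lt.lifetime_analysis(
            static,
            fixed_long,
            frame_time=long_cfg.frame_interval,
            min_frames=cfg["min_frames_lifetime"],
            seed=seed + 501,
        )
        summary["lifetimes"] = {
            "psf_gate_px": [gate.w_lo, gate.w_hi],
            "tau_app_s": fit.tau_app,
            "tau_bleach_s": fit.tau_bleach,
            "tau_bound_s": fit.tau_bound,
            "uncertainty_s": fit.uncertainty,
            "n_tracks": fit.n_tracks,
        }

    if cfg["exposure"] in ("long", "both"):
        do_lifetimes()

    if out_dir:
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
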