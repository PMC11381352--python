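"""Trajectory-focus distances, g(r) normalization, near/far split."""

import numpy as np
import pytest
from scipy import stats

from smtrack import colocalization as coloc
from smtrack import synthetic as syn
from smtrack.geometry import uniform_points_in_cell
from smtrack.synthetic import FociSet
from smtrack.tracks import Track


def _static_track(x, y, cell_id=0, track_id=0, n=5):
    return Track(
        track_id=track_id,
        cell_id=cell_id,
        frames=np.arange(n),
        x=np.full(n, x),
        y=np.full(n, y),
    )


class TestTrajectoryDistances:
    def test_track_at_focus_zero(self):
        foci = {0: FociSet(cell_id=0, centroids=[[1.0, 1.0]])}
        recs = coloc.trajectory_focus_distances([_static_track(1.0, 1.0)], foci)
        assert recs[0].distance == 0.0

    def test_constant_offset_track(self):
        foci = {0: FociSet(cell_id=0, centroids=[[1.0, 1.0]])}
        recs = coloc.trajectory_focus_distances([_static_track(1.3, 1.0)], foci)
        assert recs[0].distance == pytest.approx(0.3)

    def test_nearest_of_two_foci(self):
        foci = {0: FociSet(cell_id=0, centroids=[[1.2, 1.0], [1.5, 1.0]])}
        recs = coloc.trajectory_focus_distances([_static_track(1.0, 1.0)], foci)
        assert recs[0].distance == pytest.approx(0.2)

    def test_cells_without_foci_skipped(self):
        foci = {0: FociSet(cell_id=0, centroids=np.empty((0, 2)))}
        recs = coloc.trajectory_focus_distances([_static_track(1.0, 1.0)], foci)
        assert recs == []

    def test_mean_position_mode(self):
        t = Track(track_id=0, cell_id=0, frames=[0, 1], x=[0.8, 1.2], y=[1.0, 1.0])
        foci = {0: FociSet(cell_id=0, centroids=[[1.0, 1.0]])}
        d_mean_pos = coloc.trajectory_focus_distances([t], foci, mode="mean_position")
        d_mean_dist = coloc.trajectory_focus_distances([t], foci)
        assert d_mean_pos[0].distance == pytest.approx(0.0, abs=1e-12)
        assert d_mean_dist[0].distance == pytest.approx(0.2)


class TestRandomDistances:
    def test_same_seed_identical(self, unit_cell):
        foci = {0: syn.place_foci(unit_cell, n_foci=2, jitter=0.0, seed=1)}
        a = coloc.random_distances([unit_cell], foci, {0: 50}, seed=9)
        b = coloc.random_distances([unit_cell], foci, {0: 50}, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_zero_requested_empty(self, unit_cell):
        foci = {0: syn.place_foci(unit_cell, n_foci=1, jitter=0.0, seed=1)}
        assert len(coloc.random_distances([unit_cell], foci, {0: 0}, seed=1)) == 0

    def test_distance_distribution_matches_geometric_oracle(self, unit_cell, rng):
        # focus at the cell centroid: compare the sampler's nearest-focus
        # distances to a brute-force uniform grid over the same polygon
        cx, cy = unit_cell.polygon.centroid.coords[0]
        foci = {0: FociSet(cell_id=0, centroids=[[cx, cy]])}
        d = coloc.random_distances([unit_cell], foci, {0: 10**4}, seed=10)
        minx, miny, maxx, maxy = unit_cell.polygon.bounds
        gx, gy = np.meshgrid(
            np.linspace(minx, maxx, 400), np.linspace(miny, maxy, 100)
        )
        inside = unit_cell.contains_xy(gx.ravel(), gy.ravel())
        ref = np.hypot(gx.ravel()[inside] - cx, gy.ravel()[inside] - cy)
        ks = stats.ks_2samp(d, ref)
        assert ks.pvalue > 0.01


class TestRadialDistribution:
    @pytest.fixture(scope="class")
    def small_world(self):
        rng = np.random.default_rng(3)
        cells = syn.make_cells(60, seed=3)
        foci = {c.cell_id: syn.place_foci(c, seed=rng) for c in cells}
        counts = {c.cell_id: 25 for c in cells}
        return cells, foci, counts

    def test_uniform_null_g_near_one(self, small_world):
        cells, foci, counts = small_world
        exp = coloc.random_distances(cells, foci, counts, seed=77)
        g = coloc.radial_distribution(exp, cells, foci, counts, n_repeats=60, seed=5)
        ok = g.valid
        frac = np.mean(np.abs(g.g[ok] - 1.0) < 3.0 * g.repeat_sd[ok])
        assert frac >= 0.95

    def test_enriched_placement_first_bins_high(self, small_world):
        cells, foci, counts = small_world
        rng = np.random.default_rng(6)
        # all "molecules" within 50 nm of a focus
        exp = []
        for c in cells:
            for _ in range(counts[c.cell_id]):
                exp.append(rng.uniform(0, 0.05))
        g = coloc.radial_distribution(
            np.array(exp), cells, foci, counts, n_repeats=40, seed=8
        )
        # first bin with a usable random denominator in most repeats
        usable = g.n_defined >= g.n_repeats // 2
        first = np.flatnonzero(usable)[0]
        assert g.r[first] <= 0.05  # enrichment bins are resolvable
        assert g.g[first] > 3.0
        assert g.g[first] > np.nanmax(g.g[usable][5:])

    def test_identical_seed_control_exactly_one(self, small_world):
        cells, foci, counts = small_world
        exp = coloc.random_distances(cells, foci, counts, seed=123)
        # one repeat drawn with the same seed reproduces the same distances
        rnd = coloc.random_distances(cells, foci, counts, seed=123)
        edges = np.arange(0, 1.025, 0.025)
        he, _ = np.histogram(exp, bins=edges, density=True)
        hr, _ = np.histogram(rnd, bins=edges, density=True)
        sel = hr > 0
        np.testing.assert_allclose(he[sel] / hr[sel], 1.0)

    def test_scale_invariance_nm_vs_um(self, small_world):
        cells, foci, counts = small_world
        exp = coloc.random_distances(cells, foci, counts, seed=55)
        g_um = coloc.radial_distribution(
            exp, cells, foci, counts, bin_width=0.05, r_max=1.0, n_repeats=20, seed=9
        )
        # same data expressed in nm with bins relabeled accordingly
        import copy

        cells_nm = []
        foci_nm = {}
        from smtrack.geometry import CellOutline

        for c in cells:
            cells_nm.append(
                CellOutline(
                    cell_id=c.cell_id,
                    vertices=c.vertices * 1e3,
                    pole_a=c.pole_a * 1e3,
                    pole_b=c.pole_b * 1e3,
                    length=c.length * 1e3,
                    width=c.width * 1e3,
                )
            )
            f = foci[c.cell_id]
            foci_nm[c.cell_id] = FociSet(cell_id=c.cell_id, centroids=f.centroids * 1e3)
        g_nm = coloc.radial_distribution(
            exp * 1e3, cells_nm, foci_nm, counts, bin_width=50.0, r_max=1000.0,
            n_repeats=20, seed=9,
        )
        np.testing.assert_allclose(g_nm.g[g_nm.valid], g_um.g[g_um.valid], rtol=1e-9)

    def test_sem_shrinks_with_repeats(self, small_world):
        cells, foci, counts = small_world
        exp = coloc.random_distances(cells, foci, counts, seed=88)
        g1 = coloc.radial_distribution(exp, cells, foci, counts, n_repeats=25, seed=10)
        g2 = coloc.radial_distribution(exp, cells, foci, counts, n_repeats=100, seed=10)
        sel = g1.valid & g2.valid
        assert np.nanmedian(g2.sem[sel]) < np.nanmedian(g1.sem[sel])

    def test_bad_params_rejected(self, small_world):
        cells, foci, counts = small_world
        with pytest.raises(ValueError):
            coloc.radial_distribution([0.1], cells, foci, counts, bin_width=0.0)
        with pytest.raises(ValueError):
            coloc.radial_distribution([0.1], cells, foci, counts, n_repeats=1)


class TestRandomControl:
    def test_control_near_one_in_well_sampled_bins(self):
        rng = np.random.default_rng(4)
        cells = syn.make_cells(100, seed=4)
        foci = {c.cell_id: syn.place_foci(c, seed=rng) for c in cells}
        counts = {c.cell_id: 100 for c in cells}
        g = coloc.random_control_gr(cells, foci, counts, n_repeats=30, seed=11)
        # bins with >= 100 expected counts: per-bin relative error << 0.2
        edges = np.arange(0, 1.025, 0.025)
        ref = coloc.random_distances(cells, foci, counts, seed=12)
        counts_per_bin, _ = np.histogram(ref, bins=edges)
        # 3-sigma binomial bound: |g-1| < 3/sqrt(count); bins with >= 225
        # expected counts give a 0.2 band
        well = g.valid & (counts_per_bin >= 225)
        assert well.sum() > 10
        assert np.nanmax(np.abs(g.g[well] - 1.0)) < 0.2
        loose = g.valid & (counts_per_bin >= 100)
        assert np.nanmax(np.abs(g.g[loose] - 1.0)) < 0.3


class TestSplitByDistance:
    def test_boundary_convention(self, unit_cell):
        foci = {0: FociSet(cell_id=0, centroids=[[2.0, 1.85]])}
        near_t = _static_track(2.1, 1.85, track_id=0)  # 0.1 μm
        far_t = _static_track(2.3, 1.85, track_id=1)  # 0.3 μm
        edge_t = _static_track(2.2, 1.85, track_id=2)  # exactly 0.2 μm
        near, far = coloc.split_by_distance([near_t, far_t, edge_t], foci)
        assert [t.track_id for t in near] == [0]
        assert sorted(t.track_id for t in far) == [1, 2]
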