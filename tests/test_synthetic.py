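"""Generator contracts: geometry, foci placement, track statistics, rendering."""

import numpy as np
import pytest
from scipy import stats

from smtrack import diffusion as diff
from smtrack import synthetic as syn
from smtrack.geometry import uniform_points_in_cell


class TestMakeCells:
    def test_zero_variance_cell_has_exact_dimensions(self, unit_cell):
        minx, miny, maxx, maxy = unit_cell.polygon.bounds
        assert maxx - minx == pytest.approx(3.5, abs=1e-9)
        assert maxy - miny == pytest.approx(0.7, abs=1e-9)
        assert np.hypot(*(unit_cell.pole_b - unit_cell.pole_a)) == pytest.approx(3.5)
        assert len(unit_cell.vertices) >= 32

    def test_poles_lie_on_or_inside_polygon(self, unit_cell):
        assert bool(unit_cell.contains_xy(*unit_cell.pole_a))
        assert bool(unit_cell.contains_xy(*unit_cell.pole_b))

    def test_same_seed_identical_vertices(self):
        a = syn.make_cells(5, seed=7)
        b = syn.make_cells(5, seed=7)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.vertices, cb.vertices)

    def test_sample_mean_length_matches_distribution(self):
        cells = syn.make_cells(200, (3.48, 0.4), (0.695, 0.05), seed=3)
        lengths = np.array([c.length for c in cells])
        se = 0.4 / np.sqrt(200)
        assert abs(lengths.mean() - 3.48) < 3 * se

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            syn.make_cells(1, (-1.0, 0.0), (0.7, 0.0))
        with pytest.raises(ValueError):
            syn.make_cells(0)


class TestPlaceFoci:
    def test_no_jitter_quarter_positions(self, unit_cell):
        foci = syn.place_foci(unit_cell, n_foci=2, jitter=0.0, seed=0)
        # normalized long-axis fractions of the two centroids
        u = (foci.centroids[:, 0] - unit_cell.pole_a[0]) / unit_cell.length
        v = (foci.centroids[:, 1] - unit_cell.pole_a[1]) / unit_cell.width + 0.5
        assert sorted(np.round(u, 9)) == [0.25, 0.75]
        np.testing.assert_allclose(v, 0.5)

    def test_mean_focus_count_matches_bernoulli_mix(self):
        rng = np.random.default_rng(11)
        cells = syn.make_cells(500, seed=11)
        counts = [len(syn.place_foci(c, p_two=0.67, seed=rng)) for c in cells]
        # 1 + Bernoulli(0.67): mean 1.67, binomial SE ~ 0.021
        assert np.mean(counts) == pytest.approx(1.67, abs=0.07)

    def test_jittered_foci_stay_inside_polygon(self, unit_cell):
        rng = np.random.default_rng(5)
        for _ in range(50):
            foci = syn.place_foci(unit_cell, n_foci=2, jitter=0.3, seed=rng)
            for x, y in foci.centroids:
                assert bool(unit_cell.contains_xy(x, y))


class TestSimulateTracks:
    def test_frozen_molecule_all_localizations_identical(self, unit_cell):
        cfg = syn.SimulationConfig(
            states=((1.0, 0.0),),
            loc_noise_sigma=0.0,
            blink_prob=0.0,
            n_molecules=5,
            rng_seed=1,
        )
        tracks, _ = syn.simulate_tracks(unit_cell, None, cfg)
        for t in tracks:
            assert np.ptp(t.x) == 0 and np.ptp(t.y) == 0

    def test_observed_duration_mean_matches_bleach_lifetime(self):
        # ceil-quantized Exp(1.10 s) at 0.25 s frames has mean ~1.227 s
        durs = []
        rng = np.random.default_rng(8)
        cell = syn.make_cells(1, (3.5, 0), (0.7, 0), seed=1)[0]
        cfg = syn.SimulationConfig.long_exposure(
            n_molecules=2000,
            n_frames=10**6,
            bleach_lifetime=1.10,
            bound_lifetime=float("inf"),
            rng_seed=8,
            states=((1.0, 0.0),),
        )
        tracks, gt = syn.simulate_tracks(cell, None, cfg, rng=rng)
        durs = np.array([m.frames[-1] - m.frames[0] + 1 for m in gt.molecules]) * 0.25
        dt = 0.25
        p = np.exp(-dt / 1.10)
        expected = dt / (1 - p)  # mean of the frame-quantized exponential
        assert durs.mean() == pytest.approx(expected, rel=0.10)

    def test_state_fractions_match_configuration(self):
        cfg = syn.SimulationConfig(n_cells=1, n_molecules=2000, rng_seed=9, n_frames=30)
        cell = syn.make_cells(1, seed=2)[0]
        _, gt = syn.simulate_tracks(cell, None, cfg)
        labels = np.array([m.state_index for m in gt.molecules])
        for i, (frac, _) in enumerate(cfg.states):
            se = np.sqrt(frac * (1 - frac) / 2000)
            assert abs(np.mean(labels == i) - frac) < 4 * se

    def test_noiseless_positions_inside_cell(self, unit_cell):
        cfg = syn.SimulationConfig(
            loc_noise_sigma=0.0, n_molecules=30, rng_seed=3, n_frames=60
        )
        tracks, gt = syn.simulate_tracks(unit_cell, None, cfg)
        for m in gt.molecules:
            assert np.all(unit_cell.contains_xy(m.true_x, m.true_y))

    def test_blinking_gaps_at_most_one_frame(self, unit_cell):
        cfg = syn.SimulationConfig(blink_prob=0.4, n_molecules=50, rng_seed=4)
        tracks, _ = syn.simulate_tracks(unit_cell, None, cfg)
        for t in tracks:
            assert np.all(np.diff(t.frames) <= 2)

    def test_track_durations_exponential(self):
        cfg = syn.SimulationConfig.long_exposure(
            n_cells=1,
            n_molecules=2000,
            n_frames=10**6,
            bleach_lifetime=1.10,
            bound_lifetime=float("inf"),
            rng_seed=13,
            states=((1.0, 0.0),),
        )
        cell = syn.make_cells(1, seed=5)[0]
        _, gt = syn.simulate_tracks(cell, None, cfg)
        n_frames = np.array([m.frames[-1] - m.frames[0] + 1 for m in gt.molecules])
        # frame counts are geometric with survival p = exp(-dt/tau); compare
        # observed counts to the geometric pmf with a chi-square test
        p = np.exp(-0.25 / 1.10)
        kmax = 15
        obs = np.array(
            [np.sum(n_frames == k) for k in range(1, kmax)] + [np.sum(n_frames >= kmax)]
        )
        pmf = np.array([p ** (k - 1) * (1 - p) for k in range(1, kmax)])
        expected = len(n_frames) * np.append(pmf, p ** (kmax - 1))
        res = stats.chisquare(obs, expected)
        assert res.pvalue > 0.01

    def test_identical_seeds_identical_output(self, unit_cell):
        cfg = syn.SimulationConfig(n_molecules=10, rng_seed=6)
        t1, _ = syn.simulate_tracks(unit_cell, None, cfg)
        t2, _ = syn.simulate_tracks(unit_cell, None, cfg)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.frames, b.frames)


class TestFreeMixture:
    def test_mean_dstar_matches_true_d_without_noise(self):
        tracks, _ = syn.simulate_mixture_tracks(
            5000, states=((1.0, 0.98),), n_steps=4, dt=0.0147, seed=21
        )
        ests = diff.apparent_d_all(tracks, 0.0147)
        assert np.mean([e.d_star for e in ests]) == pytest.approx(0.98, rel=0.03)

    def test_noise_floor_raises_dstar_by_sigma2_over_dt(self):
        sigma, dt = 0.03, 0.0147
        tracks, _ = syn.simulate_mixture_tracks(
            5000, states=((1.0, 0.0),), n_steps=4, dt=dt, loc_sigma=sigma, seed=22
        )
        ests = diff.apparent_d_all(tracks, dt)
        # E[D*] = sigma^2/dt for an immobile molecule with per-axis noise sigma
        assert np.mean([e.d_star for e in ests]) == pytest.approx(
            sigma**2 / dt, rel=0.05
        )


class TestFixedCells:
    def test_zero_noise_fixed_tracks_are_frozen(self):
        cfg = syn.SimulationConfig(n_cells=3, loc_noise_sigma=0.0, rng_seed=31)
        _, tracks, _ = syn.simulate_fixed_cells(cfg)
        for t in tracks:
            assert np.ptp(t.x) == 0 and np.ptp(t.y) == 0

    def test_offset_distribution_matches_injected_noise(self, fixed_tracks_short):
        offs = np.concatenate([t.x - t.x.mean() for t in fixed_tracks_short if len(t) > 5])
        assert len(offs) >= 10**3
        assert np.std(offs) == pytest.approx(0.0265, rel=0.05)


class TestRenderMovie:
    def test_blank_movie_expected_value_offset_plus_background(self, unit_cell):
        cfg = syn.SimulationConfig(rng_seed=0)
        stack = syn.render_movie([unit_cell], None, [], cfg, n_frames=1,
                                 poisson_noise=False)
        img = stack.data[0].astype(float)
        assert np.allclose(img, cfg.camera_offset + cfg.render_background)

    def test_single_spot_argmax_at_true_pixel(self, unit_cell):
        cfg = syn.SimulationConfig(rng_seed=0)
        x0, y0 = unit_cell.uv_to_xy(0.5, 0.5)
        from smtrack.tracks import Track

        tr = Track(track_id=0, cell_id=0, frames=[0], x=[float(x0)], y=[float(y0)],
                   psf_width=[1.4], amplitude=[500.0])
        stack = syn.render_movie([unit_cell], None, [tr], cfg, n_frames=1,
                                 poisson_noise=False)
        row, col = np.unravel_index(np.argmax(stack.data[0]), stack.data[0].shape)
        tc, trow = stack.xy_to_colrow(x0, y0)
        assert abs(row - trow) <= 0.5 and abs(col - tc) <= 0.5

    def test_movie_is_16bit(self, unit_cell):
        cfg = syn.SimulationConfig(rng_seed=0)
        stack = syn.render_movie([unit_cell], None, [], cfg, n_frames=2)
        assert stack.data.dtype == np.uint16


def test_uniform_sampler_is_uniform(unit_cell, rng):
    pts = uniform_points_in_cell(unit_cell, 4000, rng)
    assert np.all(unit_cell.contains_xy(pts[:, 0], pts[:, 1]))
    # long-axis marginal of a spherocylinder: flat in the cylindrical part
    u = (pts[:, 0] - unit_cell.pole_a[0]) / unit_cell.length
    mid = u[(u > 0.2) & (u < 0.8)]
    ks = stats.kstest(mid, stats.uniform(loc=0.2, scale=0.6).cdf)
    assert ks.pvalue > 0.01


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        syn.SimulationConfig(states=((0.5, 0.1), (0.4, 0.5)))  # fractions != 1
    with pytest.raises(ValueError):
        syn.SimulationConfig(frame_interval=0.01, integration_time=0.02)
    with pytest.raises(ValueError):
        syn.SimulationConfig(pixel_size=0.0)
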