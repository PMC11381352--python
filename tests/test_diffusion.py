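"""MSD/D*, three-species mixture, static classification, jump-length model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from smtrack import diffusion as diff
from smtrack import synthetic as syn
from smtrack.tracks import Track


def _steps_track(step=0.1, n=5, frames=None):
    frames = np.arange(n) if frames is None else np.asarray(frames)
    x = np.arange(len(frames)) * step
    return Track(track_id=0, cell_id=0, frames=frames, x=x, y=np.zeros_like(x))


class TestMsd:
    def test_constant_step_hand_value(self):
        # five localizations stepping 0.1 μm in x: MSD = 0.01 μm²
        assert diff.track_msd(_steps_track()) == pytest.approx(0.01)

    def test_constant_position_zero(self):
        t = Track(track_id=0, cell_id=0, frames=[0, 1, 2], x=[1, 1, 1], y=[2, 2, 2])
        assert diff.track_msd(t) == 0.0

    def test_gap_pair_excluded(self):
        # frames 0,1,2,4,5 with equal 0.1 μm steps between consecutive frames:
        # the 2->4 displacement spans a gap and must not contaminate the MSD
        t = Track(
            track_id=0,
            cell_id=0,
            frames=[0, 1, 2, 4, 5],
            x=[0.0, 0.1, 0.2, 0.4, 0.5],
            y=np.zeros(5),
        )
        assert diff.track_msd(t) == pytest.approx(0.01)

    def test_no_consecutive_pair_raises(self):
        t = Track(track_id=0, cell_id=0, frames=[0, 2, 4], x=[0, 1, 2], y=[0, 0, 0])
        with pytest.raises(ValueError):
            diff.track_msd(t)


class TestApparentD:
    def test_arithmetic_from_printed_formula(self):
        est = diff.apparent_d(_steps_track(), dt=0.0147)
        assert est.d_star == pytest.approx(0.01 / (4 * 0.0147))
        assert est.d_star == pytest.approx(0.1701, abs=5e-4)

    def test_frozen_track_zero(self):
        t = Track(track_id=0, cell_id=0, frames=range(5), x=np.ones(5), y=np.ones(5))
        assert diff.apparent_d(t, 0.0147).d_star == 0.0

    def test_long_track_truncated_to_first_four_steps(self, rng):
        x = np.cumsum(rng.normal(0, 0.1, 12))
        t = Track(track_id=0, cell_id=0, frames=np.arange(12), x=x, y=np.zeros(12))
        t5 = Track(track_id=0, cell_id=0, frames=np.arange(5), x=x[:5], y=np.zeros(5))
        assert diff.apparent_d(t, 0.0147).d_star == diff.apparent_d(t5, 0.0147).d_star

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            diff.apparent_d(_steps_track(n=4), 0.0147)
        with pytest.raises(ValueError):
            diff.apparent_d(_steps_track(), 0.0)


class TestThreeSpeciesPdf:
    @given(
        d=st.tuples(*[st.floats(0.01, 5.0)] * 3),
        a12=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization_property(self, d, a12):
        a1 = a12[0] * 0.5
        a2 = a12[1] * (1 - a1)
        a3 = 1 - a1 - a2
        val, _ = quad(
            diff.three_species_pdf, 0, np.inf, args=(a1, a2, a3, *d), limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("d", [0.08, 0.23, 0.98])
    def test_single_species_mode_at_3d_over_4(self, d):
        xs = np.linspace(1e-4, 5 * d, 20001)
        pdf = diff.three_species_pdf(xs, 1.0, 0.0, 0.0, d, 1.0, 1.0)
        assert xs[np.argmax(pdf)] == pytest.approx(0.75 * d, rel=1e-3)

    @pytest.mark.parametrize("d", [0.08, 0.98])
    def test_single_species_mean_equals_d(self, d):
        mean, _ = quad(
            lambda x: x * diff.three_species_pdf(x, 1.0, 0.0, 0.0, d, 1.0, 1.0),
            0,
            np.inf,
            limit=200,
        )
        assert mean == pytest.approx(d, rel=1e-6)

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            diff.three_species_pdf(0.1, 1, 0, 0, -0.5, 1, 1)


class TestFitThreeSpecies:
    def test_single_species_degenerate_recovery(self):
        tracks, _ = syn.simulate_mixture_tracks(
            5000, states=((1.0, 0.5),), n_steps=4, dt=0.0147, seed=17
        )
        d_stars = [e.d_star for e in diff.apparent_d_all(tracks, 0.0147)]
        fit = diff.fit_three_species(d_stars)
        # components at ~identical D are interchangeable, so assert that the
        # total weight within 10% of the true D absorbs (nearly) everything
        w = sum(a for a, d in zip(fit.a, fit.d) if abs(d - 0.5) < 0.05)
        assert w >= 0.9

    def test_amplitudes_sum_to_one_and_d_sorted(self):
        tracks, _ = syn.simulate_mixture_tracks(2000, n_steps=4, seed=18)
        d_stars = [e.d_star for e in diff.apparent_d_all(tracks, 0.0147)]
        fit = diff.fit_three_species(d_stars)
        assert sum(fit.a) == pytest.approx(1.0, abs=1e-9)
        assert fit.d[0] <= fit.d[1] <= fit.d[2]

    def test_order_invariance(self):
        tracks, _ = syn.simulate_mixture_tracks(3000, n_steps=4, seed=19)
        d_stars = np.array([e.d_star for e in diff.apparent_d_all(tracks, 0.0147)])
        f1 = diff.fit_three_species(d_stars)
        f2 = diff.fit_three_species(d_stars[::-1])
        assert f1.a == pytest.approx(f2.a, abs=1e-6)
        assert f1.d == pytest.approx(f2.d, rel=1e-6)

    def test_binning_insensitivity(self):
        tracks, _ = syn.simulate_mixture_tracks(5000, n_steps=4, seed=20)
        d_stars = [e.d_star for e in diff.apparent_d_all(tracks, 0.0147)]
        f1 = diff.fit_three_species(d_stars, bin_width=0.05)
        f2 = diff.fit_three_species(d_stars, bin_width=0.03)
        assert np.allclose(f1.a, f2.a, atol=0.05)
        assert np.allclose(f1.d, f2.d, rtol=0.15)


class TestClassifyStatic:
    @pytest.mark.parametrize(
        "dstar,label", [(0.05, "static"), (0.14, "mobile"), (0.0, "static"), (0.2, "mobile")]
    )
    def test_threshold_is_strict(self, dstar, label):
        est = diff.DiffusionEstimate(track_id=0, d_star=dstar, n_steps=4, dt=0.0147)
        assert diff.classify_static([est])[0] == label


class TestJumpLengths:
    def test_frozen_track_step_cdf_at_zero(self):
        t = Track(track_id=0, cell_id=0, frames=range(6), x=np.ones(6), y=np.ones(6))
        cdfs = diff.jump_length_cdfs([t])
        for k, (grid, cdf, n) in cdfs.items():
            assert n > 0
            assert np.all(cdf == 1.0)  # all jumps are zero -> CDF jumps at 0

    def test_brownian_jumps_rayleigh(self):
        d, dt = 0.5, 0.0147
        tracks, _ = syn.simulate_mixture_tracks(
            2500, states=((1.0, d),), n_steps=8, dt=dt, seed=23
        )
        jumps = []
        for t in tracks:
            dx = np.diff(t.x)
            dy = np.diff(t.y)
            jumps.extend(np.hypot(dx, dy)[:4])
        ks = stats.kstest(jumps, stats.rayleigh(scale=math.sqrt(2 * d * dt)).cdf)
        assert ks.pvalue > 0.01

    def test_jump_at_max_jump_excluded(self):
        t = Track(track_id=0, cell_id=0, frames=[0, 1], x=[0.0, 5.05], y=[0.0, 0.0])
        cdfs = diff.jump_length_cdfs([t])
        assert cdfs[1][2] == 0

    def test_jumps_to_consider_caps_per_track(self):
        t = _steps_track(step=0.1, n=20)
        cdfs = diff.jump_length_cdfs([t], jumps_to_consider=4)
        assert cdfs[1][2] == 4


class TestPStay:
    def test_monotone_in_lag_and_d(self):
        lags = [0.0147 * k for k in (1, 2, 3, 4)]
        by_lag = [diff.p_stay(0.88, s, 0.7) for s in lags]
        assert all(a >= b for a, b in zip(by_lag, by_lag[1:]))
        by_d = [diff.p_stay(d, 0.0147, 0.7) for d in (0.1, 1.0, 5.0)]
        assert all(a >= b for a, b in zip(by_d, by_d[1:]))

    def test_infinite_slab_no_loss(self):
        assert diff.p_stay(5.0, 1.0, np.inf) == 1.0


class TestFitTwoState:
    def test_all_static_limit(self):
        tracks, _ = syn.simulate_mixture_tracks(
            800, states=((1.0, 0.001),), n_steps=8, dt=0.0147, loc_sigma=0.01, seed=24
        )
        fit = diff.fit_two_state(
            diff.jump_length_cdfs(tracks), loc_error=0.01, dz=np.inf
        )
        assert fit.f_bound >= 0.95

    def test_two_state_recovery(self):
        tracks, _ = syn.simulate_mixture_tracks(
            2500,
            states=((0.4, 0.02), (0.6, 0.88)),
            n_steps=8,
            dt=0.0147,
            loc_sigma=0.037,
            seed=25,
        )
        fit = diff.fit_two_state(
            diff.jump_length_cdfs(tracks), loc_error=0.037, dz=np.inf
        )
        assert fit.f_bound == pytest.approx(0.4, abs=0.05)
        assert fit.d_free == pytest.approx(0.88, rel=0.15)
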