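"""Boundary tracking, kymographs, wave tracking and the persistence estimate."""

import numpy as np
import pytest
from skimage.draw import disk

from amoebokinetics.boundary_dynamics import (build_contour_series,
                                              classify_and_track_waves,
                                              contour_area,
                                              estimate_persistence_time,
                                              extract_and_resample,
                                              fit_front_rear, kymographs,
                                              leading_edge_lifetimes,
                                              link_frames, wrap_angle,
                                              _curvature,
                                              _front_rear_templates)
from amoebokinetics.synthetic_data import (ShapeMovieSpec, WaveEvent,
                                           make_prw1d, make_shape_movie)


def disc_movie(centers, radius=50, shape=(256, 256)):
    masks = np.zeros((len(centers),) + shape, dtype=bool)
    for t, c in enumerate(centers):
        rr, cc = disk(c, radius, shape=shape)
        masks[t, rr, cc] = True
    return masks


def perimeter(points):
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


class TestExtractAndResample:
    def test_disc_perimeter_and_spacing(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        assert perimeter(pts) == pytest.approx(2 * np.pi * 50, rel=0.02)
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        assert seg.std() / seg.mean() < 0.01

    def test_start_point_is_upper_left(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        # first point lies on the topmost boundary row (y = row coordinate)
        assert pts[0, 1] == pytest.approx(pts[:, 1].min(), abs=1.5)

    def test_rejects_bad_masks(self):
        with pytest.raises(ValueError):
            extract_and_resample(np.zeros((32, 32), dtype=bool))
        two = np.zeros((64, 64), dtype=bool)
        two[5:15, 5:15] = True
        two[40:50, 40:50] = True
        with pytest.raises(ValueError):
            extract_and_resample(two)

    def test_square_has_four_curvature_peaks(self):
        sq = np.zeros((200, 200), dtype=bool)
        sq[50:150, 50:150] = True
        c = _curvature(extract_and_resample(sq, 500))
        # local maxima on the ring above half the global max
        above = c > 0.5 * c.max()
        n_runs = int(np.sum(above & ~np.roll(above, 1)))
        assert n_runs == 4

    def test_circle_curvature_constant(self):
        for R in (50, 60):
            mask = np.zeros((256, 256), dtype=bool)
            rr, cc = disk((128, 128), R)
            mask[rr, cc] = True
            c = _curvature(extract_and_resample(mask, 500))
            assert c.mean() == pytest.approx(1.0 / R, rel=0.05)
            assert c.std() / c.mean() < 0.05


class TestLinkFrames:
    def test_identity(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        shift, re = link_frames(pts, pts)
        assert shift == 0
        np.testing.assert_array_equal(re, pts)

    def test_recovers_known_offset(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        for k in (3, 117, 499):
            rolled = np.roll(pts, -k, axis=0)
            shift, re = link_frames(pts, rolled)
            np.testing.assert_allclose(re, pts, atol=1e-12)
            assert shift == (500 - k) % 500

    def test_matches_brute_force_for_translation(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        curr = np.roll(pts + [3.0, -2.0], -41, axis=0)
        shift, _ = link_frames(pts, curr)
        costs = [np.sum((pts - np.roll(curr, -s, axis=0)) ** 2)
                 for s in range(500)]
        assert shift == int(np.argmin(costs))

    def test_inverse_consistency(self, disc_mask):
        pts = extract_and_resample(disc_mask, 500)
        curr = np.roll(pts + [1.0, 2.0], -77, axis=0)
        s_ab, _ = link_frames(pts, curr)
        s_ba, _ = link_frames(curr, pts)
        assert (s_ab + s_ba) % 500 == 0


class TestKymographs:
    def test_stationary_disc(self):
        masks = disc_movie([(128, 128)] * 3)
        series = build_contour_series(masks, 1.0, 1.0)
        ky = kymographs(series)
        np.testing.assert_allclose(ky.curvature, 1 / 50.0, rtol=0.08)
        assert np.abs(ky.normal_velocity).max() < 0.05

    def test_translating_disc_projects_speed(self):
        masks = disc_movie([(100, 70 + 8 * t) for t in range(4)])
        series = build_contour_series(masks, 1.0, 1.0)
        u = series.normal_velocity[1]
        pred = 8.0 * np.cos(series.normal_angle[1])
        assert np.max(np.abs(u - pred)) < 0.35  # rasterization tolerance
        np.testing.assert_allclose(series.psi[1], 0.0, atol=0.02)

    def test_expanding_circle_uniform_velocity(self):
        masks = np.zeros((3, 256, 256), dtype=bool)
        for t, R in enumerate((40, 44, 48)):
            rr, cc = disk((128, 128), R)
            masks[t, rr, cc] = True
        series = build_contour_series(masks, 1.0, 1.0)
        np.testing.assert_allclose(series.normal_velocity, 4.0, atol=0.5)

    def test_closed_contour_circulation(self):
        """Integral of curvature along the closed boundary is 2*pi per frame."""
        spec = ShapeMovieSpec(n_frames=4, family="split",
                              waves=[WaveEvent(0.0, 1.0, 0.05)])
        masks, _ = make_shape_movie(spec, seed=2)
        series = build_contour_series(masks, 1.0, 0.2)
        for t in range(series.n_frames):
            per = perimeter(series.points[t])
            circ = series.curvature[t].sum() * per / series.n_points
            assert circ == pytest.approx(2 * np.pi, rel=0.02)

    def test_area_flux_balance(self):
        """Mask-area change per frame matches the boundary flux integral."""
        spec = ShapeMovieSpec(n_frames=6, family="fan",
                              waves=[WaveEvent(0.0, 0.3, 0.04, amplitude=0.18)])
        masks, _ = make_shape_movie(spec, seed=3)
        series = build_contour_series(masks, 1.0, 0.2)
        areas = masks.sum(axis=(1, 2)) * 0.2 ** 2
        for t in range(5):
            per = perimeter(series.points[t])
            flux = series.normal_velocity[t].sum() * per / series.n_points
            dA = areas[t + 1] - areas[t]
            assert flux == pytest.approx(dA, abs=0.05 * max(abs(dA), 1.0) + 0.6)


class TestFrontRearFit:
    def test_recovers_own_model_exactly(self):
        n, L, i1 = 500, 140, 380
        front, rear = _front_rear_templates(L, n)
        u = np.roll(3.0 * front + 1.2 * rear, i1)
        fit = fit_front_rear(u)
        assert (fit.i1, fit.i2) == (i1, (i1 + L) % n)
        assert fit.A1 == pytest.approx(3.0, rel=1e-9)
        assert fit.A2 == pytest.approx(1.2, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_translating_disc_front_faces_motion(self):
        masks = disc_movie([(100, 70 + 8 * t) for t in range(3)])
        series = build_contour_series(masks, 1.0, 1.0)
        fit = fit_front_rear(series.normal_velocity[0])
        c = int(round(fit.center_front)) % 500
        front_angle = series.normal_angle[0][c]
        assert abs(wrap_angle(front_angle - series.psi[0])) < 0.10
        rear_angle = series.normal_angle[0][int(round(fit.center_rear)) % 500]
        assert abs(wrap_angle(rear_angle - series.psi[0] - np.pi)) < 0.15

    def test_front_and_rear_angles_on_moving_cell(self):
        """On a translating deforming cell the front normals cluster at the
        motion direction and the rear normals opposite."""
        spec = ShapeMovieSpec(n_frames=12, family="fan", image_size=320,
                              velocity_um_s=(0.8, 0.0))
        masks, _ = make_shape_movie(spec, seed=4)
        series = build_contour_series(masks, 1.0, 0.2)
        fronts, rears = [], []
        for t in range(series.n_frames - 1):
            fit = fit_front_rear(series.normal_velocity[t])
            fronts.append(wrap_angle(
                series.normal_angle[t][int(round(fit.center_front)) % 500]
                - series.psi[t]))
            rears.append(wrap_angle(
                series.normal_angle[t][int(round(fit.center_rear)) % 500]
                - series.psi[t]))
        assert np.abs(np.mean(np.exp(1j * np.array(fronts)))) > 0.9
        assert np.mean(np.abs(fronts)) < 0.5
        assert np.mean(np.abs(np.abs(rears) - np.pi)) < 0.6

    def test_degenerate_profile_flagged(self):
        fit = fit_front_rear(np.zeros(500))
        assert fit.degenerate


class TestWaveTracking:
    def make_synthetic_kymograph(self, n=500, T=60, omega=0.05, dt=1.0):
        """Gaussian curvature bump whose center advances at a known angular
        velocity on a circular contour (normal angle = 2*pi*i/n)."""
        idx = np.arange(n)
        phi = wrap_angle(2 * np.pi * idx / n)
        curv = np.zeros((n, T))
        for t in range(T):
            center = (0.5 + omega * t * dt) * n / (2 * np.pi)
            d = np.minimum(np.abs(idx - center % n),
                           n - np.abs(idx - center % n))
            curv[:, t] = 0.02 + 0.08 * np.exp(-0.5 * (d / 12.0) ** 2)
        phi_k = np.tile(phi[:, None], (1, T))
        return curv, phi_k

    def test_recovers_programmed_angular_velocity(self):
        curv, phi_k = self.make_synthetic_kymograph()
        track = classify_and_track_waves(curv, phi_k, dt=1.0)
        assert track.c1 < track.c2
        assert track.omegas.mean() == pytest.approx(0.05, rel=0.05)
        assert track.omega_c == pytest.approx(0.05, rel=0.10)

    def test_two_disjoint_bumps_give_two_unmixed_fragments(self):
        n, T = 500, 10
        idx = np.arange(n)
        curv = np.zeros((n, T))
        for c0 in (100, 350):
            d = np.minimum(np.abs(idx - c0), n - np.abs(idx - c0))
            curv += 0.08 * np.exp(-0.5 * (d / 10.0) ** 2)[:, None]
        phi_k = np.tile(wrap_angle(2 * np.pi * idx / n)[:, None], (1, T))
        track = classify_and_track_waves(curv, phi_k, dt=1.0)
        assert all(len(f) == 2 for f in track.fragments)
        for (t, j, jp) in track.links:
            assert j == jp  # no cross-links between disjoint bumps

    def test_fragments_match_brute_force_labeling(self):
        rng = np.random.default_rng(13)
        curv = rng.standard_normal((500, 5))
        phi_k = np.zeros((500, 5))
        track = classify_and_track_waves(curv, phi_k, dt=1.0)
        for t in range(5):
            mask = curv[:, t] > track.c2
            # brute force: connected components on the doubled ring
            doubled = np.concatenate([mask, mask])
            runs = []
            start = None
            for i, val in enumerate(doubled):
                if val and start is None:
                    start = i
                elif not val and start is not None:
                    if start < 500:
                        runs.append((start, i - 1))
                    start = None
            expected = {(s % 500, e % 500) for s, e in runs
                        if e - s < 500 and not (s == 0 and mask[499])}
            got = set(track.fragments[t])
            if mask.all():
                assert got == {(0, 499)}
            else:
                assert got == expected

    def test_otsu_thresholds_shift_with_constant(self):
        rng = np.random.default_rng(14)
        curv = rng.normal(0.0, 1.0, (500, 8)) + np.where(
            rng.random((500, 8)) < 0.2, 3.0, 0.0)
        phi_k = np.zeros((500, 8))
        t1 = classify_and_track_waves(curv, phi_k, 1.0)
        t2 = classify_and_track_waves(curv + 5.0, phi_k, 1.0)
        assert t2.c1 - t1.c1 == pytest.approx(5.0, abs=0.05)
        assert t2.c2 - t1.c2 == pytest.approx(5.0, abs=0.05)

    def test_constant_curvature_yields_no_waves(self):
        with pytest.warns(UserWarning):
            track = classify_and_track_waves(np.full((500, 5), 0.02),
                                             np.zeros((500, 5)), 1.0)
        assert len(track.links) == 0


class TestLeadingEdge:
    def test_single_persistent_wave_single_lifetime(self):
        curv, phi_k = TestWaveTracking().make_synthetic_kymograph(T=40,
                                                                  omega=0.0)
        track = classify_and_track_waves(curv, phi_k, dt=1.0)
        psi = np.full(40, 0.5)  # constant motion direction
        jd, lifetimes, tau_d = leading_edge_lifetimes(track, psi)
        assert (jd >= 0).all()
        assert len(lifetimes) == 1
        assert lifetimes[0] == pytest.approx(39.0)  # (T-1) * dt

    def test_alternating_waves_have_programmed_lifetimes(self):
        """Two fixed waves with the leading role switching every K frames."""
        n, T, K = 500, 60, 6
        idx = np.arange(n)
        curv = np.zeros((n, T))
        for c0 in (100, 350):
            d = np.minimum(np.abs(idx - c0), n - np.abs(idx - c0))
            curv += 0.08 * np.exp(-0.5 * (d / 10.0) ** 2)[:, None]
        phi_k = np.tile(wrap_angle(2 * np.pi * idx / n)[:, None], (1, T))
        track = classify_and_track_waves(curv, phi_k, dt=1.0)
        ang = [wrap_angle(2 * np.pi * 100 / n), wrap_angle(2 * np.pi * 350 / n)]
        psi = np.array([ang[(t // K) % 2] for t in range(T)])
        jd, lifetimes, tau_d = leading_edge_lifetimes(track, psi)
        inner = lifetimes[1:-1]
        np.testing.assert_allclose(inner, K - 1.0)

    def test_movie_recovery_of_programmed_wave_persistence(self):
        """Sequential waves born at the front with a programmed lifetime; the
        leading-edge lifetime estimate matches it within 15%."""
        life = 8.0
        # alternate sides so successive waves never overlap in index space
        waves = [WaveEvent(birth_time=k * life, theta0=0.7 * (-1) ** k,
                           angular_speed=0.0, lifetime=life, width=0.25)
                 for k in range(10)]
        spec = ShapeMovieSpec(n_frames=80, family="disc", image_size=384,
                              velocity_um_s=(0.15, 0.0), waves=waves)
        masks, _ = make_shape_movie(spec, seed=5)
        series = build_contour_series(masks, 1.0, 0.2)
        ky = kymographs(series)
        track = classify_and_track_waves(ky.curvature, ky.normal_angle, 1.0)
        jd, lifetimes, tau_d = leading_edge_lifetimes(track, series.psi)
        # the lifetime statistic subtracts one frame interval by construction
        assert np.mean(lifetimes) + 1.0 == pytest.approx(life, rel=0.15)


class TestPersistenceTime:
    def test_reference_value(self):
        assert estimate_persistence_time(0.1, 2.8) == pytest.approx(142.9,
                                                                    abs=0.1)

    def test_scaling_law(self):
        base = estimate_persistence_time(0.05, 4.0)
        assert estimate_persistence_time(0.10, 4.0) == pytest.approx(base / 4)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            estimate_persistence_time(0.0, 1.0)

    def test_monte_carlo_agreement(self):
        """The direction autocorrelation of the angle walk decays with the
        closed-form time 4/(omega^2 tau) within 10%."""
        omega, tau = 0.1, 2.8
        times, psi = make_prw1d(omega, tau, 600.0, seed=6, n_walkers=4000)
        ac = np.mean(np.cos(psi - psi[:, :1]), axis=0)
        sel = (times > 10) & (times < 300)
        slope = np.polyfit(times[sel], np.log(ac[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(
            estimate_persistence_time(omega, tau), rel=0.10)
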