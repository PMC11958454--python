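"""Sub-pixel localization, linking, MSD and diffusion estimation."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from slimquant.config import SimulationConfig
from slimquant.simulate import (AggregateGroundTruth, render_stack,
                                simulate_brownian_track)
from slimquant.tracking import (Localization, LocalizationError, MSDCurve,
                                compute_msd, estimate_diffusion, link_tracks,
                                localize_focus)


def _render_single(x_px, y_px, cfg=None, n_mol=1, noise=False, seed=0):
    cfg = cfg or SimulationConfig(n_frames=1, image_shape=(41, 41), rng_seed=seed)
    px = cfg.pixel_size_um
    truth = AggregateGroundTruth(0, n_mol, 0.0, np.array([[x_px * px, y_px * px]]),
                                 np.full(n_mol, np.inf), np.zeros(n_mol, dtype=bool))
    return render_stack(cfg, [truth], noise=noise).movie[0], cfg


class TestLocalize:
    def test_noiseless_subpixel_recovery(self):
        img, cfg = _render_single(41.70, 20.30, SimulationConfig(
            n_frames=1, image_shape=(41, 61)))
        loc = localize_focus(img + 10.0, (20, 42), sigma_px=cfg.psf_sigma_px)
        assert abs(loc.x - 41.70) < 1e-2
        assert abs(loc.y - 20.30) < 1e-2

    def test_flat_image_rejected(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(10, size=(41, 41)).astype(float)
        with pytest.raises(LocalizationError):
            localize_focus(img, (20, 20), sigma_px=0.725)

    def test_precision_scales_inverse_sqrt_photons(self):
        # quadrupling the photon budget should halve the RMS error; the
        # 1/sqrt(N) law holds in the shot-noise-dominated (low-background)
        # regime, so the background is set near zero here
        rng = np.random.default_rng(1)
        rms = {}
        for photons in (150.0, 600.0):
            errs = []
            for i in range(250):
                x = 20 + rng.uniform(-0.5, 0.5)
                y = 20 + rng.uniform(-0.5, 0.5)
                cfg = SimulationConfig(n_frames=1, image_shape=(41, 41),
                                       photons_per_fluorophore_per_frame=photons,
                                       background_photons=1.0, read_noise_sd=0.3,
                                       rng_seed=int(rng.integers(2**31)))
                img, _ = _render_single(x, y, cfg, noise=True)
                loc = localize_focus(img, (20, 20), sigma_px=cfg.psf_sigma_px,
                                     snr_min=2.0)
                errs.append((loc.x - x) ** 2 + (loc.y - y) ** 2)
            rms[photons] = np.sqrt(np.mean(errs))
        ratio = rms[150.0] / rms[600.0]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_integer_translation_equivariance(self):
        img, cfg = _render_single(20.37, 19.64, noise=True, seed=5)
        big = np.pad(img, ((6, 0), (9, 0)), mode="wrap")
        a = localize_focus(img, (20, 20), sigma_px=cfg.psf_sigma_px)
        b = localize_focus(big, (26, 29), sigma_px=cfg.psf_sigma_px)
        assert b.x - a.x == pytest.approx(9.0, abs=1e-9)
        assert b.y - a.y == pytest.approx(6.0, abs=1e-9)


def _loc(frame, x, y):
    return Localization(frame=frame, x=x, y=y, fitted_sigma=1.0, amplitude=1.0,
                        local_background=0.0, summed_intensity=1.0,
                        precision_estimate=1.0)


class TestLinking:
    def test_single_persistent_focus_one_track(self):
        locs = {t: [_loc(t, 10 + 0.3 * t, 5.0)] for t in range(20)}
        tracks = link_tracks(locs, max_disp=5.0)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_jump_beyond_max_disp_splits_track(self):
        locs = {0: [_loc(0, 0, 0)], 1: [_loc(1, 1, 0)], 2: [_loc(2, 30, 0)]}
        tracks = link_tracks(locs, max_disp=5.0)
        assert sorted(len(t) for t in tracks) == [1, 2]

    def test_well_separated_pair_no_identity_switch(self):
        rng = np.random.default_rng(2)
        truth_a = np.cumsum(rng.normal(0, 0.5, (50, 2)), axis=0) + [0, 0]
        truth_b = np.cumsum(rng.normal(0, 0.5, (50, 2)), axis=0) + [200, 0]
        locs = {t: [_loc(t, *truth_a[t]), _loc(t, *truth_b[t])] for t in range(50)}
        tracks = link_tracks(locs, max_disp=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            xs = np.array([l.x for l in tr.localizations])
            assert np.ptp(xs) < 100  # never hops to the far aggregate

    def test_greedy_matches_optimal_on_small_frames(self):
        # with <=6 spots per frame, total greedy link cost should match the
        # optimal assignment on well-posed (separated) configurations
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 7)
            a = rng.uniform(0, 100, (n, 2))
            b = a + rng.normal(0, 0.3, (n, 2))
            locs = {0: [_loc(0, *p) for p in a], 1: [_loc(1, *p) for p in b]}
            tracks = link_tracks(locs, max_disp=5.0)
            greedy_cost = 0.0
            for tr in tracks:
                if len(tr) == 2:
                    p, q = tr.localizations
                    greedy_cost += np.hypot(p.x - q.x, p.y - q.y)
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            ri, ci = linear_sum_assignment(d)
            assert greedy_cost == pytest.approx(d[ri, ci].sum(), rel=1e-6)


class TestMSD:
    def test_constant_position_zero_msd(self):
        msd = compute_msd(np.zeros((30, 2)), frame_interval=0.005)
        assert np.all(msd.msd == 0)

    def test_constant_velocity_quadratic(self):
        v = 2.0  # µm/s
        dt = 0.005
        pos = np.stack([v * dt * np.arange(100), np.zeros(100)], axis=1)
        msd = compute_msd(pos, frame_interval=dt, n_max=10)
        expected = (v * msd.intervals) ** 2
        assert msd.msd == pytest.approx(expected, rel=1e-9)

    def test_brownian_msd_matches_4dDt(self):
        tr = simulate_brownian_track(1.0, 10001, 0.005, (0, 0), rng=4)
        msd = compute_msd(tr, frame_interval=0.005, n_max=1)
        assert msd.msd[0] == pytest.approx(4 * 1.0 * 0.005, rel=0.10)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(np.zeros((1, 2)))


class TestDiffusion:
    def test_exact_line_recovered(self):
        dt = np.arange(1, 7) * 0.005
        msd = MSDCurve(intervals=dt, msd=4 * 0.99 * dt, n_pairs=np.full(6, 50))
        est = estimate_diffusion(msd, n_points=4)
        assert est.d_coeff == pytest.approx(0.99, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_immobile_emitter_intercept_reads_localization_noise(self):
        sigma_loc = 0.04  # µm
        rng = np.random.default_rng(6)
        ds, intercepts = [], []
        for _ in range(300):
            pos = rng.normal(0, sigma_loc, (60, 2))
            est = estimate_diffusion(compute_msd(pos, frame_interval=0.005, n_max=8), 4)
            ds.append(est.d_coeff)
            intercepts.append(est.intercept)
        assert abs(np.mean(ds)) < 0.05
        assert np.mean(intercepts) == pytest.approx(4 * sigma_loc**2, rel=0.30)

    def test_ensemble_recovery_at_unit_diffusion(self):
        rng = np.random.default_rng(7)
        ds = []
        for _ in range(200):
            tr = simulate_brownian_track(1.0, 60, 0.005, (0, 0), rng=rng)
            ds.append(estimate_diffusion(
                compute_msd(tr, frame_interval=0.005, n_max=10), 4).d_coeff)
        assert 0.9 <= np.mean(ds) <= 1.1

    def test_few_points_warns(self):
        dt = np.arange(1, 3) * 0.005
        msd = MSDCurve(intervals=dt, msd=4 * dt, n_pairs=np.array([5, 4]))
        with pytest.warns(UserWarning):
            est = estimate_diffusion(msd, n_points=4)
        assert est.n_points_used == 2
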