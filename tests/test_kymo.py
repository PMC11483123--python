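import numpy as np
import pytest

from vesiclefuse.io import Epoch, EpochTimeline, MovieStack
from vesiclefuse.kymo import (FrapCurve, MobilityParams, PunctumTrack,
                              build_kymograph, classify_mobility,
                              cotravel_fraction, frap_recovery, moving_fraction,
                              track_puncta)
from vesiclefuse.simulate import SceneConfig, condition_preset, make_scene, render_movie


def track_from(positions_um, frame_rate=2.0, channel="A"):
    pos = np.asarray(positions_um, dtype=float)
    return PunctumTrack(channel, np.arange(len(pos)), pos, frame_rate)


def spot_movie(track_px, shape=(32, 200), n_frames=None, background=100.0,
               amp=80.0, sigma=1.3):
    """Noiseless movie of one spot moving along the horizontal midline."""
    n_frames = n_frames or len(track_px)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    frames = []
    for k in range(n_frames):
        c = track_px[min(k, len(track_px) - 1)]
        frames.append(background + amp * np.exp(
            -((rr - shape[0] / 2) ** 2 + (cc - c) ** 2) / (2 * sigma**2)))
    return MovieStack(np.stack(frames))


class TestBuildKymograph:
    def test_stationary_spot_vertical_ridge(self):
        movie = spot_movie([80.0] * 30)
        path = np.array([[16.0, 5.0], [16.0, 195.0]])
        kg = build_kymograph(movie, path, 5)
        ridge = kg.data.argmax(axis=1)
        assert np.ptp(ridge) == 0

    def test_slope_matches_speed(self):
        # 1 um/s at 0.2 um/px and 2 Hz = 2.5 px/frame
        movie = spot_movie([20.0 + 2.5 * k for k in range(40)])
        path = np.array([[16.0, 5.0], [16.0, 195.0]])
        kg = build_kymograph(movie, path, 5)
        ridge = kg.data.argmax(axis=1).astype(float)
        slope_um_s = np.polyfit(np.arange(40) / 2.0, ridge * 0.2, 1)[0]
        assert slope_um_s == pytest.approx(1.0, rel=0.10)

    def test_degenerate_path_rejected(self):
        movie = spot_movie([80.0] * 5)
        with pytest.raises(ValueError):
            build_kymograph(movie, np.array([[16.0, 50.0], [16.0, 50.0]]), 5)

    def test_even_width_rejected(self):
        movie = spot_movie([80.0] * 5)
        with pytest.raises(ValueError, match="odd"):
            build_kymograph(movie, np.array([[16.0, 5.0], [16.0, 60.0]]), 4)

    def test_path_outside_image_rejected(self):
        movie = spot_movie([80.0] * 5)
        with pytest.raises(ValueError, match="bounds"):
            build_kymograph(movie, np.array([[16.0, 5.0], [64.0, 60.0]]), 5)


class TestClassifyMobility:
    def test_zero_displacement_immobile(self):
        tr = classify_mobility(track_from(np.full(60, 5.0)))
        assert not tr.mobile

    def test_constant_motion_mobile(self):
        """1 um/s for 20 s: any 10-s window displaces 10 um >= 0.75 um."""
        tr = classify_mobility(track_from(np.arange(40) * 0.5))
        assert tr.mobile
        assert tr.max_window_disp_um == pytest.approx(10.0)

    def test_small_jitter_immobile(self):
        rng = np.random.default_rng(0)
        tr = classify_mobility(track_from(5.0 + rng.normal(0, 0.1, 240)))
        assert not tr.mobile

    def test_threshold_boundary(self):
        # exactly 0.75 um over a 10-s window counts as moving
        pos = np.concatenate([np.zeros(10), np.linspace(0, 0.75, 20),
                              np.full(30, 0.75)])
        assert classify_mobility(track_from(pos)).mobile

    def test_short_track_flagged(self):
        tr = classify_mobility(track_from(np.arange(10) * 0.5))
        assert tr.flagged_short

    def test_classifier_accuracy_on_noisy_tracks(self):
        """>= 95% accuracy for speeds >= 0.3 um/s vs jitter SD <= 0.1 um."""
        rng = np.random.default_rng(1)
        correct = total = 0
        for i in range(100):
            mobile = i % 2 == 0
            if mobile:
                speed = rng.uniform(0.3, 2.0)
                pos = np.arange(240) * speed / 2.0
            else:
                pos = np.zeros(240)
            pos = pos + rng.normal(0, 0.1, 240)
            tr = classify_mobility(track_from(pos))
            correct += tr.mobile == mobile
            total += 1
        assert correct / total >= 0.95


class TestMovingFraction:
    def test_arithmetic(self):
        tracks = [classify_mobility(track_from(np.arange(40) * 0.5))] * 47 + \
                 [classify_mobility(track_from(np.zeros(40)))] * 53
        assert moving_fraction(tracks) == pytest.approx(0.47)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            moving_fraction([])

    def test_recovers_simulated_mobile_fraction(self, transport_scene):
        cfg, truth, movie, _ = transport_scene
        kg = build_kymograph(movie, truth.neurite_paths[0], 5)
        tracks = track_puncta(kg)
        assert tracks, "tracking found no puncta"
        truth_frac = np.mean([v.mobile for v in truth.vesicles])
        assert moving_fraction(tracks) == pytest.approx(truth_frac, abs=0.35)


class TestCotravel:
    def test_identical_channels_fully_cotravel(self):
        tracks = [classify_mobility(track_from(np.arange(60) * 0.4 + i * 10))
                  for i in range(3)]
        fa, fb = cotravel_fraction(tracks, tracks, pixel_size_um=0.2)
        assert fa == 1.0 and fb == 1.0

    def test_stationary_partner_never_cotravels(self):
        a = [classify_mobility(track_from(np.arange(60) * 0.4))]
        b = [classify_mobility(track_from(np.full(60, 5.0)))]
        fa, fb = cotravel_fraction(a, b, pixel_size_um=0.2)
        assert fa == 0.0 and np.isnan(fb)  # B has no moving tracks

    def test_ground_truth_recovery(self):
        """20% of moving A vesicles carry a B label; the recovered fraction
        pooled over seeds stays within 10 percentage points."""
        num = den = t_num = t_den = 0
        for seed in range(10):
            cfg = condition_preset("NPY-like", seed=seed, cotravel_b_fraction=0.2)
            tl = EpochTimeline((Epoch("baseline", 0, cfg.duration_s),))
            truth = make_scene(cfg, tl)
            mA = render_movie(truth, cfg, tl, channel="A")
            mB = render_movie(truth, cfg, tl, channel="B")
            path = truth.neurite_paths[0]
            tA = track_puncta(build_kymograph(mA, path, 5), channel="A")
            tB = track_puncta(build_kymograph(mB, path, 5), channel="B")
            fab, _ = cotravel_fraction(tA, tB, cfg.pixel_size_um)
            n_mov = sum(t.mobile for t in tA)
            if not np.isnan(fab) and n_mov:
                num += fab * n_mov
                den += n_mov
            mob = [v for v in truth.vesicles if v.mobile]
            t_num += sum("B" in v.channels for v in mob)
            t_den += len(mob)
        assert abs(num / den - t_num / t_den) <= 0.10


class TestFrap:
    def frap_setup(self, seed=4, tau=20.0):
        cfg = SceneConfig(field_px=(64, 64), n_vesicles=0, duration_s=150.0,
                          bleach_region=(16, 48, 16, 48), bleach_efficiency=0.9,
                          frap_exchange_amp=80.0, frap_exchange_tau_s=tau, seed=seed)
        tl = EpochTimeline((Epoch("baseline", 0, 30), Epoch("bleach", 30, 31),
                            Epoch("post_stim", 31, 150)))
        truth = make_scene(cfg, tl)
        return cfg, tl, render_movie(truth, cfg, tl)

    def test_exponential_exchange_recovery(self):
        cfg, tl, movie = self.frap_setup()
        curve = frap_recovery(movie, tl, cfg.bleach_region)
        expect = 1 - np.exp(-(curve.t_s + 1.0) / 20.0)
        expect = (expect - expect[0]) / (expect.max() - expect[0])
        assert np.max(np.abs(curve.values - expect)) < 0.10
        assert curve.half_time_s == pytest.approx(np.log(2) * 20.0, abs=3.0)

    def test_normalization_affine_invariant(self):
        cfg, tl, movie = self.frap_setup()
        scaled = MovieStack(movie.data * 3.0 + 50.0, movie.frame_rate_hz,
                            movie.pixel_size_um)
        a = frap_recovery(movie, tl, cfg.bleach_region)
        b = frap_recovery(scaled, tl, cfg.bleach_region)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_raw_curve_unnormalized(self):
        cfg, tl, movie = self.frap_setup()
        raw = frap_recovery(movie, tl, cfg.bleach_region, normalize=False)
        assert raw.values.max() > 50  # camera units, not [0, 1]

    def test_no_recovery_flagged_flat(self):
        data = np.full((100, 32, 32), 100.0)
        data[60:] = 20.0  # bleach with zero recovery, zero noise
        movie = MovieStack(data)
        tl = EpochTimeline((Epoch("baseline", 0, 30), Epoch("bleach", 30, 30.5),))
        curve = frap_recovery(movie, tl, (8, 24, 8, 24))
        assert curve.flagged_flat
        assert (curve.values == 0).all()

    def test_missing_bleach_rejected(self):
        movie = MovieStack(np.ones((10, 8, 8)))
        with pytest.raises(ValueError, match="bleach"):
            frap_recovery(movie, EpochTimeline((Epoch("baseline", 0, 5),)),
                          (0, 8, 0, 8))
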