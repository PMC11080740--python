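"""Simulator: planted-event construction, determinism, geometry invariants."""
import math

import numpy as np
import pandas as pd
import pytest

from evhotspot import SimulationConfig, simulate_movie, simulate_nfat_image
from evhotspot.simulate import match_to_ground_truth

from conftest import single_event_config


class TestSimulateMovie:
    def test_no_events_is_pure_background(self):
        cfg = SimulationConfig(n_events=0, noise_sigma=0.0, frames=10, seed=1)
        movie, truth = simulate_movie(cfg)
        assert truth.empty
        assert np.all(movie.data == cfg.background_level)

    def test_single_flash_spikes_once_at_centroid(self):
        cfg = single_event_config("flash")
        movie, truth = simulate_movie(cfg)
        diff = movie.data[1:] - movie.data[:-1]
        onset = int(truth["onset_frame"].iloc[0])
        k = int(np.argmax(diff.max(axis=(1, 2))))
        assert k == onset - 1
        # the maximum sits at the centroid pixel and equals the planted
        # Gaussian evaluated there (sub-pixel placement attenuates the peak)
        cx = truth["x_um"].iloc[0] / cfg.pixel_size
        cy = truth["y_um"].iloc[0] / cfg.pixel_size
        iy, ix = np.unravel_index(np.argmax(diff[k]), diff[k].shape)
        assert (ix, iy) == (round(cx), round(cy))
        sig_px = truth["sigma_um"].iloc[0] / cfg.pixel_size
        d2 = (ix - cx) ** 2 + (iy - cy) ** 2
        expected = truth["amplitude"].iloc[0] * math.exp(-d2 / (2 * sig_px**2))
        assert diff[k].max() == pytest.approx(expected, rel=1e-9)
        # the spike is gone one frame later: equally strong negative blob
        assert diff[k + 1].min() == pytest.approx(-expected, rel=1e-9)

    def test_identical_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=7, hotspot_fraction=0.4, sync_fraction=0.5)
        m1, t1 = simulate_movie(cfg)
        m2, t2 = simulate_movie(cfg)
        assert m1.data.tobytes() == m2.data.tobytes()
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        m1, _ = simulate_movie(SimulationConfig(seed=1))
        m2, _ = simulate_movie(SimulationConfig(seed=2))
        assert not np.array_equal(m1.data, m2.data)

    def test_flash_mass_matches_gaussian_integral(self):
        cfg = single_event_config("flash")
        movie, truth = simulate_movie(cfg)
        onset = int(truth["onset_frame"].iloc[0])
        mass = (movie.data[onset] - cfg.background_level).sum()
        sig_px = truth["sigma_um"].iloc[0] / cfg.pixel_size
        expected = truth["amplitude"].iloc[0] * 2.0 * math.pi * sig_px**2
        assert mass == pytest.approx(expected, rel=0.02)

    def test_fade_follows_exponential_envelope(self):
        cfg = single_event_config("fade", fade_tau_range=(10.0, 10.0))
        movie, truth = simulate_movie(cfg)
        onset = int(truth["onset_frame"].iloc[0])
        cx = int(round(truth["x_um"].iloc[0] / cfg.pixel_size))
        cy = int(round(truth["y_um"].iloc[0] / cfg.pixel_size))
        trace = movie.data[:, cy, cx] - cfg.background_level
        t = np.arange(onset, movie.n_frames)
        expected = trace[onset] * np.exp(-(t - onset) * cfg.frame_interval / 10.0)
        np.testing.assert_allclose(trace[onset:], expected, rtol=1e-9)

    def test_stay_persists_to_end(self):
        cfg = single_event_config("stay")
        movie, truth = simulate_movie(cfg)
        onset = int(truth["onset_frame"].iloc[0])
        cx = int(round(truth["x_um"].iloc[0] / cfg.pixel_size))
        cy = int(round(truth["y_um"].iloc[0] / cfg.pixel_size))
        trace = movie.data[:, cy, cx]
        assert np.allclose(trace[onset:], trace[onset])
        assert trace[onset] > trace[0]

    def test_one_hotspot_full_sync_shares_onset_and_stays_close(self):
        cfg = SimulationConfig(
            n_events=4, hotspot_fraction=1.0, sync_fraction=1.0, seed=3
        )
        _, truth = simulate_movie(cfg)
        assert truth["hotspot_id"].nunique() == 1
        assert truth["onset_frame"].nunique() == 1
        xy = truth[["x_um", "y_um"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        assert d.max() <= 2.0 * cfg.hotspot_radius + 1e-9

    def test_events_inside_cell_and_onsets_detectable(self):
        cfg = SimulationConfig(seed=5, n_events=25, hotspot_fraction=0.5)
        movie, truth = simulate_movie(cfg)
        centre = np.array([cfg.width, cfg.height]) / 2.0 * cfg.pixel_size
        r = np.hypot(truth["x_um"] - centre[0], truth["y_um"] - centre[1])
        assert (r <= cfg.cell_radius + 1e-9).all()
        assert truth["onset_frame"].between(1, cfg.frames - 1).all()

    def test_overlap_dominated_config_rejected(self):
        cfg = SimulationConfig(n_events=200)
        with pytest.raises(ValueError, match="density"):
            simulate_movie(cfg)

    def test_bad_class_mix_rejected(self):
        cfg = SimulationConfig(class_mix={"stay": 0.5, "fade": 0.5, "flash": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_movie(cfg)

    def test_bleaching_decays_background(self):
        cfg = SimulationConfig(
            n_events=0, noise_sigma=0.0, bleach_rate=0.01, frames=10, seed=1
        )
        movie, _ = simulate_movie(cfg)
        levels = movie.data[:, 0, 0]
        np.testing.assert_allclose(levels, 100.0 * 0.99 ** np.arange(10))


class TestSimulateNfat:
    def test_ratio_one_means_equal_compartments(self):
        image, nuc, cyt, _ = simulate_nfat_image(4, nc_ratio=1.0, noise_sigma=0.0, seed=1)
        for cid in range(1, 5):
            assert image[nuc == cid].mean() == pytest.approx(image[cyt == cid].mean())

    def test_planted_ratio_exact_without_noise(self):
        image, nuc, cyt, true_ratios = simulate_nfat_image(
            6, nc_ratio=3.0, noise_sigma=0.0, seed=2
        )
        for cid in range(1, 7):
            ratio = image[nuc == cid].mean() / image[cyt == cid].mean()
            assert ratio == pytest.approx(3.0, rel=1e-12)
        assert np.all(true_ratios == 3.0)

    def test_monte_carlo_recovery_within_5pct(self):
        ratios = []
        for seed in range(20):
            image, nuc, cyt, _ = simulate_nfat_image(
                50, nc_ratio=2.0, noise_sigma=5.0, seed=seed
            )
            for cid in range(1, 51):
                ratios.append(image[nuc == cid].mean() / image[cyt == cid].mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_nucleus_must_fit_inside_cell(self):
        with pytest.raises(ValueError, match="inside"):
            simulate_nfat_image(1, nc_ratio=2.0, noise_sigma=0.0, seed=0,
                                cell_radius_px=8, nucleus_radius_px=8)


class TestMatching:
    def test_greedy_matching_is_one_to_one(self):
        truth = pd.DataFrame(
            {"x_um": [1.0, 1.2], "y_um": [1.0, 1.0], "onset_frame": [5, 5]}
        )
        det_xy = np.array([[10.0, 10.0], [11.0, 10.0]])  # px at 0.1 um/px
        m = match_to_ground_truth(truth, det_xy, np.array([5, 5]), pixel_size=0.1)
        assert m["recall"] == 1.0 and m["precision"] == 1.0
        assert sorted(p[0] for p in m["pairs"]) == [0, 1]
        assert sorted(p[1] for p in m["pairs"]) == [0, 1]

    def test_time_tolerance_enforced(self):
        truth = pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "onset_frame": [5]})
        m = match_to_ground_truth(truth, np.array([[10.0, 10.0]]), np.array([8]), 0.1)
        assert m["pairs"] == [] and m["recall"] == 0.0
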