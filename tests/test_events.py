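"""Event profiles, exclusion rules, kinetic classification and width."""
import math

import numpy as np
import pytest

from evhotspot import (
    EventParams,
    MovieStack,
    SimulationConfig,
    classify_event,
    difference_stack,
    extract_profile,
    find_candidates,
    measure_width,
    qc_filter,
    simulate_movie,
    summarize_cell,
)
from evhotspot.events import (
    QC_IRREGULAR,
    QC_LATERAL,
    QC_MINIMAL,
    QC_PASS,
    EventRecord,
)
from evhotspot.detect import EventCandidate

from conftest import single_event_config


def _first_candidate(movie, threshold=30.0):
    cands = find_candidates(difference_stack(movie), threshold=threshold)
    assert cands, "expected at least one candidate"
    return cands[0]


def _gaussian_spot_movie(track, amplitude=80.0, sigma_px=2.0, frames=40,
                         side=64, background=100.0):
    """Movie with one spot whose (x, y) position follows `track` (frame -> xy)."""
    arr = np.full((frames, side, side), background)
    yy, xx = np.mgrid[0:side, 0:side]
    for t, (cx, cy) in track.items():
        arr[t] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
        )
    return MovieStack(arr)


class TestExtractProfile:
    def test_noiseless_flash_trace_is_single_step(self):
        cfg = single_event_config("flash")
        movie, truth = simulate_movie(cfg)
        cand = _first_candidate(movie)
        prof = extract_profile(movie, cand)
        onset = int(truth["onset_frame"].iloc[0])
        assert prof.baseline == pytest.approx(cfg.background_level)
        assert prof.peak_frame == onset
        off_event = np.delete(prof.trace, onset)
        np.testing.assert_allclose(off_event, cfg.background_level, rtol=1e-9)
        assert prof.peak_delta > 0

    def test_early_onset_flags_low_confidence_baseline(self):
        track = {t: (20.0, 20.0) for t in range(1, 10)}
        movie = _gaussian_spot_movie(track, frames=10)
        cand = _first_candidate(movie)
        assert cand.onset_frame == 1
        prof = extract_profile(movie, cand)
        assert prof.low_confidence_baseline

    def test_noiseless_fade_trace_matches_envelope(self):
        cfg = single_event_config("fade", fade_tau_range=(10.0, 10.0))
        movie, truth = simulate_movie(cfg)
        prof = extract_profile(movie, _first_candidate(movie))
        onset = int(truth["onset_frame"].iloc[0])
        rise = prof.trace[onset:] - prof.baseline
        expected = rise[0] * np.exp(-np.arange(rise.size) * cfg.frame_interval / 10.0)
        np.testing.assert_allclose(rise, expected, rtol=0.02)


class TestQcFilter:
    def test_no_change_excluded_as_minimal(self):
        movie = MovieStack(np.full((20, 32, 32), 100.0))
        cand = EventCandidate(
            onset_frame=10, centroid=(16.0, 16.0), area=4,
            mean_diff_intensity=0.0,
            blob_rows=np.array([16]), blob_cols=np.array([16]),
        )
        prof = extract_profile(movie, cand)
        assert qc_filter(prof) == QC_MINIMAL

    def test_translating_spot_excluded_as_lateral(self):
        # spot appears at frame 10 and drifts 15 px (= 1.6 um) over its life
        track = {t: (20.0 + 0.75 * (t - 10), 20.0) for t in range(10, 30)}
        movie = _gaussian_spot_movie(track)
        prof = extract_profile(movie, _first_candidate(movie))
        assert qc_filter(prof) == QC_LATERAL

    def test_double_burst_excluded_as_irregular(self):
        # two equal bursts at one spot separated by a return to baseline
        track = {t: (20.0, 20.0) for t in list(range(8, 12)) + list(range(25, 29))}
        movie = _gaussian_spot_movie(track)
        prof = extract_profile(movie, _first_candidate(movie))
        assert qc_filter(prof) == QC_IRREGULAR

    def test_clean_fades_pass_at_snr_10(self):
        # "clean" means isolated: default cell geometry keeps events sparse
        # enough that a neighbour rarely contaminates the profile ROI
        n_pass = n_total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                frames=60, n_events=3,
                class_mix={"stay": 0.0, "fade": 1.0, "flash": 0.0},
                amplitude_range=(50.0, 50.0), noise_sigma=5.0, seed=seed,
            )
            movie, _ = simulate_movie(cfg)
            for cand in find_candidates(difference_stack(movie), threshold="auto"):
                n_total += 1
                n_pass += qc_filter(extract_profile(movie, cand)) == QC_PASS
        assert n_total >= 40
        assert n_pass / n_total >= 0.95

    def test_qc_is_deterministic(self):
        cfg = SimulationConfig(seed=13, n_events=10)
        movie, _ = simulate_movie(cfg)
        cands = find_candidates(difference_stack(movie))
        flags1 = [qc_filter(extract_profile(movie, c)) for c in cands]
        flags2 = [qc_filter(extract_profile(movie, c)) for c in cands]
        assert flags1 == flags2


class TestClassifyEvent:
    @pytest.mark.parametrize("event_class", ["flash", "stay"])
    def test_planted_class_recovered_noiseless(self, event_class):
        cfg = single_event_config(event_class)
        movie, truth = simulate_movie(cfg)
        prof = extract_profile(movie, _first_candidate(movie))
        cls, _, _ = classify_event(prof, cfg.frame_interval)
        assert cls == event_class

    @pytest.mark.parametrize("tau", [5.0, 10.0, 20.0])
    def test_fade_tau_recovered_noiseless(self, tau):
        cfg = single_event_config("fade", fade_tau_range=(tau, tau), frames=120, seed=23)
        movie, truth = simulate_movie(cfg)
        if truth["onset_frame"].iloc[0] > cfg.frames - 10:  # keep a long tail
            cfg = single_event_config("fade", fade_tau_range=(tau, tau), frames=120, seed=24)
            movie, truth = simulate_movie(cfg)
        prof = extract_profile(movie, _first_candidate(movie))
        cls, tau_hat, r2 = classify_event(prof, cfg.frame_interval)
        assert cls == "fade"
        assert tau_hat == pytest.approx(tau, rel=0.02)
        assert r2 > 0.99

    def test_event_near_movie_end_is_undecidable(self):
        cfg = single_event_config("fade", fade_tau_range=(20.0, 20.0))
        movie, truth = simulate_movie(cfg)
        onset = int(truth["onset_frame"].iloc[0])
        # truncate so fewer than 3 post-peak frames remain
        short = MovieStack(
            movie.data[: onset + 2],
            pixel_size=movie.pixel_size,
            frame_interval=movie.frame_interval,
        )
        cand = _first_candidate(movie)
        prof = extract_profile(short, cand)
        cls, _, _ = classify_event(prof, cfg.frame_interval)
        assert cls == "undecidable"


class TestMeasureWidth:
    def test_noiseless_gaussian_fwhm(self):
        cfg = single_event_config("stay", spot_sigma_range=(0.2, 0.2))
        movie, _ = simulate_movie(cfg)
        prof = extract_profile(movie, _first_candidate(movie))
        width = measure_width(movie, prof)
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * 0.2  # 0.471 um
        assert width == pytest.approx(expected, abs=cfg.pixel_size)

    def test_width_ordering_tracks_spot_size(self):
        widths = []
        for sigma in (0.15, 0.30):
            cfg = single_event_config("stay", spot_sigma_range=(sigma, sigma))
            movie, _ = simulate_movie(cfg)
            prof = extract_profile(movie, _first_candidate(movie))
            widths.append(measure_width(movie, prof))
        assert widths[0] < widths[1]


class TestSummarizeCell:
    def test_empty_cell_reports_missing_proportions(self):
        s = summarize_cell([], duration_s=300.0)
        assert s["n_events"] == 0
        assert s["class_proportions"] is None

    def test_proportions_are_simple_counts(self):
        records = (
            [EventRecord(id=i, onset_frame=5, x_um=0, y_um=0, qc="pass", event_class="flash") for i in range(5)]
            + [EventRecord(id=5 + i, onset_frame=5, x_um=0, y_um=0, qc="pass", event_class="fade") for i in range(3)]
            + [EventRecord(id=8 + i, onset_frame=5, x_um=0, y_um=0, qc="pass", event_class="stay") for i in range(2)]
        )
        s = summarize_cell(records, duration_s=300.0)
        p = s["class_proportions"]
        assert p == {"stay": 0.2, "fade": 0.3, "flash": 0.5}
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)
        assert s["events_per_5min"] == 10.0

    def test_undecidable_counted_but_not_in_proportions(self):
        records = [
            EventRecord(id=0, onset_frame=5, x_um=0, y_um=0, qc="pass", event_class="flash"),
            EventRecord(id=1, onset_frame=5, x_um=0, y_um=0, qc="pass", event_class="undecidable"),
            EventRecord(id=2, onset_frame=5, x_um=0, y_um=0, qc="excluded_lateral"),
        ]
        s = summarize_cell(records, duration_s=300.0)
        assert s["n_events"] == 2
        assert s["n_undecidable"] == 1
        assert s["class_proportions"] == {"stay": 0.0, "fade": 0.0, "flash": 1.0}
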