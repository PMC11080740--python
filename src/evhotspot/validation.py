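"""Recovery benchmarks: run the pipeline on simulated movies with known truth.

Each benchmark generates seeded movies under stated conditions, runs the
relevant part of the analysis from scratch, and scores it against the
planted ground truth.  They are used by the acceptance test suite and the
acceptance script; problem sizes are chosen so each benchmark completes in
a couple of minutes on one CPU (see docs/methods.md).
"""
from __future__ import annotations

import filecmp
import math
from pathlib import Path

import numpy as np

from . import detect, events, spatial
from .config import RunConfig
from .pipeline import analyze_movie, run_pipeline
from .simulate import SimulationConfig, match_to_ground_truth, simulate_movie

#: wide-field geometry for the spatial benchmarks: at the default 256 px /
#: 12.5 um cell nearly every event has a neighbour within 5 um by chance,
#: so the planted hotspot fraction is only identifiable in a larger cell.
_WIDE = dict(
    height=512,
    width=512,
    pixel_size=2 * 0.1067,
    cell_radius=45.0,
    spot_sigma_range=(0.3, 0.5),
)


def _detect_xy_onsets(movie, cfg: RunConfig):
    diff = detect.difference_stack(movie, gap=cfg.gap)
    cands = detect.find_candidates(
        diff,
        threshold=cfg.threshold,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        k_mad=cfg.k_mad,
        merge_radius_px=cfg.merge_radius_px,
    )
    xy = np.array([c.centroid for c in cands]).reshape(-1, 2)
    onsets = np.array([c.onset_frame for c in cands], dtype=int)
    return cands, xy, onsets


def detection_benchmark(n_movies: int = 20, seed: int = 101) -> dict:
    """Recall/precision of candidate detection on default 30-event movies.

    3 px / 1 frame matching tolerance against the planted ground truth;
    amplitudes (default 40-80) are at least 8x the read-noise sigma (5).
    """
    cfg = RunConfig()
    recalls, precisions = [], []
    n_true = n_det = 0
    for i in range(n_movies):
        sim = SimulationConfig(seed=seed + i, hotspot_fraction=0.3)
        movie, truth = simulate_movie(sim)
        _, xy, onsets = _detect_xy_onsets(movie, cfg)
        m = match_to_ground_truth(truth, xy, onsets, movie.pixel_size)
        recalls.append(m["recall"])
        precisions.append(m["precision"])
        n_true += m["n_true"]
        n_det += m["n_detected"]
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "n_true": n_true,
        "n_detected": n_det,
        "n_movies": n_movies,
    }


def classification_benchmark(n_movies: int = 20, seed: int = 202) -> dict:
    """Per-class accuracy and fade-tau recovery at SNR 8, equal class mix.

    Movies are split into three batches with fixed decay constants tau in
    {5, 10, 20} s so tau recovery can be scored per value.  Accuracy is
    computed over matched, QC-passing, decidable events.
    """
    cfg = RunConfig()
    taus = [5.0, 10.0, 20.0]
    confusion: dict[str, dict[str, int]] = {
        c: {k: 0 for k in ("stay", "fade", "flash", "undecidable", "excluded")}
        for c in ("stay", "fade", "flash")
    }
    tau_recovered: dict[float, list[float]] = {t: [] for t in taus}
    params = cfg.event_params()
    for i in range(n_movies):
        tau = taus[i * len(taus) // n_movies]
        sim = SimulationConfig(
            seed=seed + i,
            class_mix={"stay": 1 / 3, "fade": 1 / 3, "flash": 1 / 3},
            amplitude_range=(40.0, 40.0),  # SNR 8 at noise_sigma 5
            fade_tau_range=(tau, tau),
        )
        movie, truth = simulate_movie(sim)
        cands, xy, onsets = _detect_xy_onsets(movie, cfg)
        m = match_to_ground_truth(truth, xy, onsets, movie.pixel_size)
        for ti, di in m["pairs"]:
            true_cls = truth["true_class"].iloc[ti]
            prof = events.extract_profile(
                movie, cands[di], roi_radius=cfg.roi_radius_px,
                baseline_window=cfg.baseline_window, candidate_id=di,
            )
            if events.qc_filter(prof, params) != events.QC_PASS:
                confusion[true_cls]["excluded"] += 1
                continue
            cls, tau_hat, _ = events.classify_event(prof, movie.frame_interval, params)
            confusion[true_cls][cls] += 1
            if true_cls == "fade" and cls == "fade" and tau_hat is not None:
                tau_recovered[tau].append(tau_hat)
    accuracy = {}
    for c in ("stay", "fade", "flash"):
        decided = sum(confusion[c][k] for k in ("stay", "fade", "flash"))
        accuracy[c] = confusion[c][c] / decided if decided else float("nan")
    tau_rel_err = {
        t: abs(float(np.mean(v)) - t) / t if v else float("nan")
        for t, v in tau_recovered.items()
    }
    return {
        "accuracy": accuracy,
        "confusion": confusion,
        "tau_rel_err": tau_rel_err,
        "max_tau_rel_err": float(np.nanmax(list(tau_rel_err.values()))),
        "n_movies": n_movies,
    }


def width_benchmark(n_movies: int = 10, events_per_movie: int = 5, seed: int = 303) -> dict:
    """Mean recovered FWHM for planted 0.2 um-sigma spots at SNR 8.

    Expected FWHM = 2*sqrt(2 ln 2)*0.2 = 0.471 um.  Persistent (stay)
    events are planted so the peak frame is well defined.
    """
    cfg = RunConfig()
    params = cfg.event_params()
    widths = []
    for i in range(n_movies):
        sim = SimulationConfig(
            seed=seed + i,
            frames=40,
            n_events=events_per_movie,
            class_mix={"stay": 1.0, "fade": 0.0, "flash": 0.0},
            amplitude_range=(40.0, 40.0),
            spot_sigma_range=(0.2, 0.2),
        )
        movie, truth = simulate_movie(sim)
        cands, xy, onsets = _detect_xy_onsets(movie, cfg)
        m = match_to_ground_truth(truth, xy, onsets, movie.pixel_size)
        for _, di in m["pairs"]:
            prof = events.extract_profile(
                movie, cands[di], roi_radius=cfg.roi_radius_px,
                baseline_window=cfg.baseline_window, candidate_id=di,
            )
            if events.qc_filter(prof, params) != events.QC_PASS:
                continue
            w = events.measure_width(movie, prof)
            if np.isfinite(w):
                widths.append(w)
    return {
        "mean_width_um": float(np.mean(widths)) if widths else float("nan"),
        "expected_width_um": 2.0 * math.sqrt(2.0 * math.log(2.0)) * 0.2,
        "n_spots": len(widths),
    }


def hotspot_benchmark(
    hotspot_fraction: float, n_movies: int = 20, seed: int = 404
) -> dict:
    """Measured localized fraction (pipeline, 5 um) vs the planted fraction."""
    cfg = RunConfig()
    fractions = []
    for i in range(n_movies):
        sim = SimulationConfig(
            seed=seed + i,
            frames=60,
            n_events=10,
            hotspot_fraction=hotspot_fraction,
            hotspot_radius=2.0,
            **_WIDE,
        )
        movie, truth = simulate_movie(sim)
        bundle = analyze_movie(movie, cfg)
        frac = bundle["spatial"]["localized_fraction"]
        if frac is not None:
            fractions.append(frac)
    return {
        "planted_pct": 100.0 * hotspot_fraction,
        "measured_pct": float(np.mean(fractions)) if fractions else float("nan"),
        "n_movies": n_movies,
    }


def synchrony_benchmark(n_movies: int = 20, seed: int = 505) -> dict:
    """Directional synchrony recovery: sync planted only inside hotspots.

    With sync_fraction 0.5 inside hotspots and none elsewhere, the
    per-event synchronized fraction among localized events should exceed
    the diffuse one in nearly every seed.
    """
    cfg = RunConfig()
    wins = comparable = 0
    for i in range(n_movies):
        sim = SimulationConfig(
            seed=seed + i,
            frames=120,
            n_events=20,
            hotspot_fraction=0.7,
            hotspot_radius=2.0,
            sync_fraction=0.5,
            **_WIDE,
        )
        movie, _ = simulate_movie(sim)
        bundle = analyze_movie(movie, cfg)
        sp = bundle["spatial"]
        loc = sp["sync_fraction_localized"]
        dif = sp["sync_fraction_diffuse"]
        if loc is None or dif is None:
            continue
        comparable += 1
        if loc > dif:
            wins += 1
    return {"wins": wins, "comparable": comparable, "n_movies": n_movies}


def nfat_benchmark(seed: int = 606, n_cells: int = 100) -> dict:
    """Batch-mean N/C ratio recovered from the two-compartment fixture."""
    from .assays import nfat_batch_summary, nfat_nc_ratio
    from .simulate import simulate_nfat_image

    image, nuc, cyt, _ = simulate_nfat_image(n_cells, nc_ratio=2.0, noise_sigma=5.0, seed=seed)
    measures = nfat_nc_ratio(image, nuc, cyt)
    out = nfat_batch_summary(measures)
    out["true_ratio"] = 2.0
    return out


def determinism_benchmark(tmp_dir: str | Path, seed: int = 707) -> dict:
    """Full pipeline twice under one seed/config; outputs must be byte-identical."""
    from .io import write_movie

    tmp = Path(tmp_dir)
    sim = SimulationConfig(seed=seed, hotspot_fraction=0.3)
    movie, truth = simulate_movie(sim)
    movie_path = tmp / "movie.tif"
    write_movie(movie, movie_path, extra={"seed": seed})
    # the simulator itself must also be bit-stable
    movie2, _ = simulate_movie(sim)
    sim_identical = bool(movie.data.tobytes() == movie2.data.tobytes())

    files_identical = True
    outs = []
    for run in ("run_a", "run_b"):
        cfg = RunConfig(movie=str(movie_path), out_dir=str(tmp / run), seed=seed)
        bundle = run_pipeline(cfg)
        outs.append(sorted(Path(tmp / run).iterdir()))
    for a, b in zip(*outs):
        if a.name != b.name or not filecmp.cmp(a, b, shallow=False):
            files_identical = False
    return {
        "simulator_bit_identical": sim_identical,
        "outputs_byte_identical": files_identical,
        "n_files": len(outs[0]),
    }
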