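"""Seeded synthetic TIRF movies with planted ground truth.

The generator emulates a single transfected cell imaged in TIRF: sparse,
diffraction-limited brightenings (membrane-fusion reporter events) appear on
a flat background and then either persist ("stay"), decay exponentially
("fade") or vanish after one frame ("flash").  Events can be placed in
clusters ("hotspots") and forced to share an onset frame ("synchronized"),
which is the spatial structure the downstream hotspot statistics recover.

Ground truth is returned as a table, one row per planted event, and is the
oracle for all recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM, MovieStack

EVENT_CLASSES = ("stay", "fade", "flash")

#: target number of events per planted hotspot
_EVENTS_PER_HOTSPOT = 4


@dataclass
class SimulationConfig:
    """Acquisition geometry, event statistics and noise model of one movie.

    Defaults reproduce the acquisition conditions of the study system:
    5-minute movies at 0.40 frames per second (120 frames, 2.5 s/frame),
    one cell per 256 x 256 field at 0.1067 um/px, with a basal class mix
    dominated by flash events.  Intensities are arbitrary camera units.
    """

    frames: int = 120
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    height: int = 256
    width: int = 256
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    n_events: int = 30
    class_mix: dict = field(
        default_factory=lambda: {"stay": 0.16, "fade": 0.16, "flash": 0.68}
    )
    amplitude_range: tuple = (40.0, 80.0)
    spot_sigma_range: tuple = (0.15, 0.30)  # um
    fade_tau_range: tuple = (5.0, 20.0)  # s
    hotspot_fraction: float = 0.0
    hotspot_radius: float = 2.0  # um
    sync_fraction: float = 0.0
    background_level: float = 100.0
    noise_sigma: float = 5.0
    bleach_rate: float = 0.0  # per-frame fractional loss of background
    cell_radius: float = 12.5  # um
    seed: int = 0

    def validate(self) -> None:
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.height < 8 or self.width < 8:
            raise ValueError("field of view too small")
        mix = {k: float(v) for k, v in self.class_mix.items()}
        if set(mix) - set(EVENT_CLASSES):
            raise ValueError(f"class_mix keys must be among {EVENT_CLASSES}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1 within 1e-9")
        if any(v < 0 for v in mix.values()):
            raise ValueError("class_mix probabilities must be >= 0")
        for name in ("hotspot_fraction", "sync_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.hotspot_radius <= 0 or self.cell_radius <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.bleach_rate < 1.0:
            raise ValueError("bleach_rate must lie in [0, 1)")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sigma must be >= 0")
        half_um = 0.5 * min(self.height, self.width) * self.pixel_size
        if self.cell_radius >= half_um:
            raise ValueError(
                f"cell_radius {self.cell_radius} um does not fit the "
                f"{self.height}x{self.width} field ({2 * half_um:.1f} um across)"
            )
        # Overlap-dominated scenes are unanalysable: reject configs whose
        # expected density exceeds one event per 4*hotspot_radius^2 um^2.
        cell_area = math.pi * self.cell_radius**2
        if self.n_events / cell_area > 1.0 / (4.0 * self.hotspot_radius**2):
            raise ValueError(
                "event density too high: expected more than one event per "
                f"{4.0 * self.hotspot_radius ** 2:.1f} um^2 on average"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplitude_range"] = list(self.amplitude_range)
        d["spot_sigma_range"] = list(self.spot_sigma_range)
        d["fade_tau_range"] = list(self.fade_tau_range)
        return d


GROUND_TRUTH_COLUMNS = [
    "event_id",
    "true_class",
    "onset_frame",
    "x_um",
    "y_um",
    "amplitude",
    "sigma_um",
    "tau_s",
    "hotspot_id",
]


def _empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in GROUND_TRUTH_COLUMNS})


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a disc of given radius, centred on the origin."""
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * math.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _temporal_envelope(
    cls: str, onset: int, frames: int, amplitude: float, tau: float, dt: float
) -> np.ndarray:
    """Per-frame peak intensity of one event from its onset to the last frame."""
    t = np.arange(onset, frames)
    if cls == "flash":
        env = np.zeros(t.size)
        env[0] = amplitude
    elif cls == "fade":
        env = amplitude * np.exp(-(t - onset) * dt / tau)
    elif cls == "stay":
        env = np.full(t.size, amplitude)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown event class {cls!r}")
    return env


def simulate_movie(config: SimulationConfig) -> tuple[MovieStack, pd.DataFrame]:
    """Render a movie with planted fusion events and return it with its truth table.

    Every event is an isotropic Gaussian spot (peak ``amplitude``, width
    ``sigma``) appearing abruptly at ``onset_frame`` with a class-specific
    temporal envelope, superposed on a constant background with optional
    per-frame bleaching and additive Gaussian read noise.  Identical config
    (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    H, W, T = config.height, config.width, config.frames
    px = config.pixel_size
    centre = np.array([W / 2.0 * px, H / 2.0 * px])  # (x, y) um

    classes = (
        rng.choice(EVENT_CLASSES, size=n, p=[config.class_mix.get(c, 0.0) for c in EVENT_CLASSES])
        if n
        else np.array([], dtype=object)
    )

    # --- spatial placement -------------------------------------------------
    n_hot = int(round(config.hotspot_fraction * n))
    n_hotspots = max(1, math.ceil(n_hot / _EVENTS_PER_HOTSPOT)) if n_hot else 0
    hotspot_centres = (
        centre + _uniform_disc(rng, n_hotspots, config.cell_radius - config.hotspot_radius)
        if n_hotspots
        else np.zeros((0, 2))
    )
    xy = np.zeros((n, 2))
    hotspot_id = np.full(n, -1, dtype=int)
    if n_hot:
        members = np.arange(n_hot) % n_hotspots  # round-robin: even occupancy
        xy[:n_hot] = hotspot_centres[members] + _uniform_disc(rng, n_hot, config.hotspot_radius)
        hotspot_id[:n_hot] = members
    if n - n_hot:
        xy[n_hot:] = centre + _uniform_disc(rng, n - n_hot, config.cell_radius)

    # --- timing ------------------------------------------------------------
    onsets = rng.integers(1, T, size=n) if n else np.array([], dtype=int)
    for h in range(n_hotspots):
        sync_frame = int(rng.integers(1, T))
        idx = np.nonzero(hotspot_id == h)[0]
        take = rng.random(idx.size) < config.sync_fraction
        onsets[idx[take]] = sync_frame

    amplitudes = rng.uniform(*config.amplitude_range, size=n)
    sigmas = rng.uniform(*config.spot_sigma_range, size=n)
    taus = rng.uniform(*config.fade_tau_range, size=n)

    # --- render ------------------------------------------------------------
    t_idx = np.arange(T, dtype=float)
    background = config.background_level * (1.0 - config.bleach_rate) ** t_idx
    movie = np.broadcast_to(background[:, None, None], (T, H, W)).copy()

    for i in range(n):
        sig_px = sigmas[i] / px
        cx, cy = xy[i] / px  # pixel coordinates, pixel-centre convention
        r = int(math.ceil(4.0 * sig_px)) + 1
        x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
        ygrid, xgrid = np.mgrid[y0:y1, x0:x1]
        spot = np.exp(-((xgrid - cx) ** 2 + (ygrid - cy) ** 2) / (2.0 * sig_px**2))
        env = _temporal_envelope(
            str(classes[i]), int(onsets[i]), T, amplitudes[i], taus[i], config.frame_interval
        )
        movie[int(onsets[i]) :, y0:y1, x0:x1] += env[:, None, None] * spot

    if config.noise_sigma > 0:
        movie += rng.normal(0.0, config.noise_sigma, size=movie.shape)
    np.clip(movie, 0.0, None, out=movie)

    truth = pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=int),
            "true_class": classes.astype(str) if n else pd.Series(dtype=str),
            "onset_frame": onsets.astype(int),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "amplitude": amplitudes,
            "sigma_um": sigmas,
            "tau_s": np.where(classes == "fade", taus, np.nan) if n else np.array([]),
            "hotspot_id": hotspot_id,
        }
    ) if n else _empty_ground_truth()

    stack = MovieStack(
        movie, pixel_size=px, frame_interval=config.frame_interval, bit_depth=16
    )
    return stack, truth


# ---------------------------------------------------------------------------
# two-compartment nuclear-translocation fixture
# ---------------------------------------------------------------------------

def simulate_nfat_image(
    n_cells: int,
    nc_ratio: float,
    noise_sigma: float,
    seed: int,
    *,
    cell_radius_px: int = 16,
    nucleus_radius_px: int = 7,
    cytoplasm_level: float = 100.0,
):
    """Synthetic field of disjoint cells for nuclear/cytoplasmic ratio recovery.

    Each cell is a disc of mean intensity ``cytoplasm_level`` containing a
    strictly interior nuclear disc of mean ``cytoplasm_level * nc_ratio``,
    plus additive Gaussian noise.  Returns ``(image, nucleus_labels,
    cytoplasm_labels, true_ratios)`` where the label images number cells
    1..n_cells and the cytoplasm label excludes the nucleus.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be positive")
    if nucleus_radius_px >= cell_radius_px:
        raise ValueError("nucleus must lie strictly inside its cytoplasm")
    rng = np.random.default_rng(seed)

    ncols = math.ceil(math.sqrt(n_cells))
    nrows = math.ceil(n_cells / ncols)
    spacing = 2 * cell_radius_px + 8
    H = nrows * spacing + spacing // 2
    W = ncols * spacing + spacing // 2
    image = np.zeros((H, W))
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    cyto_labels = np.zeros((H, W), dtype=np.int32)

    yy, xx = np.mgrid[0:H, 0:W]
    for i in range(n_cells):
        row, col = divmod(i, ncols)
        cy = spacing // 2 + cell_radius_px + row * spacing
        cx = spacing // 2 + cell_radius_px + col * spacing
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        cell = r2 <= cell_radius_px**2
        nucleus = r2 <= nucleus_radius_px**2
        image[cell] = cytoplasm_level
        image[nucleus] = cytoplasm_level * nc_ratio
        nucleus_labels[nucleus] = i + 1
        cyto_labels[cell & ~nucleus] = i + 1

    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    true_ratios = np.full(n_cells, float(nc_ratio))
    return image, nucleus_labels, cyto_labels, true_ratios


# ---------------------------------------------------------------------------
# ground-truth matching (the recovery oracle)
# ---------------------------------------------------------------------------

def match_to_ground_truth(
    truth: pd.DataFrame,
    detected_xy_px: np.ndarray,
    detected_onsets: np.ndarray,
    pixel_size: float,
    *,
    max_dist_px: float = 3.0,
    max_dt_frames: int = 1,
) -> dict:
    """Greedy one-to-one matching of detections against planted events.

    A detection matches a planted event when their centroids lie within
    ``max_dist_px`` pixels and their onset frames within ``max_dt_frames``.
    Pairs are assigned closest-first.  Returns recall, precision and the
    index pairs (truth row -> detection row).
    """
    det_xy = np.atleast_2d(np.asarray(detected_xy_px, dtype=float))
    det_on = np.asarray(detected_onsets, dtype=int)
    n_true = len(truth)
    n_det = len(det_on)
    if n_true == 0 or n_det == 0:
        return {
            "n_true": n_true,
            "n_detected": n_det,
            "pairs": [],
            "recall": 0.0 if n_true else float("nan"),
            "precision": 0.0 if n_det else float("nan"),
        }
    true_xy = truth[["x_um", "y_um"]].to_numpy() / pixel_size
    true_on = truth["onset_frame"].to_numpy(dtype=int)

    d = np.hypot(
        true_xy[:, 0][:, None] - det_xy[:, 0][None, :],
        true_xy[:, 1][:, None] - det_xy[:, 1][None, :],
    )
    dt = np.abs(true_on[:, None] - det_on[None, :])
    valid = (d <= max_dist_px) & (dt <= max_dt_frames)
    order = np.argsort(d, axis=None)
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        ti, di = divmod(int(flat), n_det)
        if not valid[ti, di]:
            continue
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((ti, di))
        if len(pairs) == min(n_true, n_det):
            break
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "pairs": pairs,
        "recall": len(pairs) / n_true,
        "precision": len(pairs) / n_det,
    }
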