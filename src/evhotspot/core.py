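"""Core calibrated-stack containers shared across the pipeline.

A single acquisition is one cell imaged in TIRF for ~5 minutes; the movie is
the unit of analysis.  All physical quantities carry explicit units: pixel
size in micrometres per pixel, frame interval in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 16 um camera pixels behind a 150x objective.
DEFAULT_PIXEL_SIZE_UM = 0.1067
#: Acquisition rate of 0.40 frames per second.
DEFAULT_FRAME_INTERVAL_S = 2.5


@dataclass
class MovieStack:
    """A T x H x W intensity stack with physical calibration.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(T, H, W)`` with ``T >= 2``.
        Stored as float64 internally regardless of the source bit depth.
    pixel_size
        Lateral calibration in micrometres per pixel.
    frame_interval
        Time between consecutive frames in seconds.
    bit_depth
        Bit depth of the source data (8 or 16); informational, used for
        saturation checks and when writing to disk.
    degenerate_range
        Set by :func:`evhotspot.detect.to_8bit` when the source stack was
        constant (zero dynamic range) and mapped to all zeros.
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    bit_depth: int = 16
    degenerate_range: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_frames * self.frame_interval


@dataclass
class DifferenceStack:
    """Signed frame-to-frame differences of a movie.

    Frame ``k`` holds ``movie[k + gap] - movie[k]``; a new, localized
    fluorescence increase therefore appears as a positive blob in the
    difference frame preceding its onset.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    gap: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("difference stack must be (T-gap) x H x W")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]
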