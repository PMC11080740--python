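"""Hotspot (localized) and synchrony statistics for single-cell event sets.

An event is *localized* when another event in the same cell lies strictly
within ``radius`` (default 5 um) of it, regardless of time separation; it is
*synchronized* when another event in the same cell shares its onset frame
(an optional frame window widens this for sensitivity analysis).  The
primary output is per-event: among localized events, what percentage are
synchronized, and likewise among diffuse events.  A per-pair convention
(fraction of close pairs that are same-frame, and of far pairs) is also
reported because the natural denominator of "percentage of synchronized
events" is ambiguous; the per-event figures are the headline ones.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

DEFAULT_RADIUS_UM = 5.0


def _distance_matrix(xy: np.ndarray) -> np.ndarray:
    # explicit elementwise sqrt(dx^2 + dy^2): bit-identical to a plain
    # per-pair loop, which the O(n^2) cross-checks rely on
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    return np.sqrt(dx * dx + dy * dy)


@dataclass
class SpatialSummary:
    """Per-movie localization and synchrony fractions (percent)."""

    n_events: int
    n_localized: int
    localized_fraction: float | None
    n_synchronized_localized: int
    n_synchronized_diffuse: int
    sync_fraction_localized: float | None
    sync_fraction_diffuse: float | None
    pair_sync_fraction_close: float | None
    pair_sync_fraction_far: float | None
    radius_um: float
    sync_window_frames: int

    def to_dict(self) -> dict:
        return asdict(self)


def pairwise_distances(xy_um: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix (um) over event centroids.

    Fewer than two events yields an empty table.
    """
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    if len(xy) < 2:
        return np.zeros((0, 0))
    return _distance_matrix(xy)


def localized_mask(xy_um: np.ndarray, radius: float = DEFAULT_RADIUS_UM) -> np.ndarray:
    """Boolean mask: event i has another event strictly within ``radius``."""
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    n = len(xy)
    if n < 2:
        return np.zeros(n, dtype=bool)
    d = _distance_matrix(xy)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) < radius


def synchronized_mask(onset_frames: np.ndarray, window: int = 0) -> np.ndarray:
    """Boolean mask: event i shares an onset frame (within ``window``) with another."""
    on = np.asarray(onset_frames, dtype=int)
    n = on.size
    if n < 2:
        return np.zeros(n, dtype=bool)
    dt = np.abs(on[:, None] - on[None, :])
    np.fill_diagonal(dt, np.iinfo(int).max)
    return dt.min(axis=1) <= window


def localized_fraction(
    xy_um: np.ndarray, radius: float = DEFAULT_RADIUS_UM
) -> tuple[int, float | None]:
    """Number of localized events and the percentage localized (None if no events)."""
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    n = len(xy)
    if n == 0:
        return 0, None
    loc = localized_mask(xy, radius)
    return int(loc.sum()), 100.0 * float(loc.sum()) / n


def summarize_spatial(
    xy_um: np.ndarray,
    onset_frames: np.ndarray,
    radius: float = DEFAULT_RADIUS_UM,
    sync_window: int = 0,
) -> SpatialSummary:
    """Full per-movie spatial summary over one cell's events."""
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    on = np.asarray(onset_frames, dtype=int)
    n = len(xy) if xy.size else 0
    if n and on.size != n:
        raise ValueError("coordinates and onset frames must align")

    loc = localized_mask(xy, radius) if n else np.zeros(0, bool)
    sync = synchronized_mask(on, sync_window) if n else np.zeros(0, bool)

    n_loc = int(loc.sum())
    n_dif = n - n_loc
    n_sync_loc = int((sync & loc).sum())
    n_sync_dif = int((sync & ~loc).sum())

    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    # per-pair convention
    pair_close = pair_far = pair_close_sync = pair_far_sync = 0
    if n >= 2:
        d = _distance_matrix(xy)
        iu = np.triu_indices(n, k=1)
        close = d[iu] < radius
        same = np.abs(on[:, None] - on[None, :])[iu] <= sync_window
        pair_close = int(close.sum())
        pair_far = int((~close).sum())
        pair_close_sync = int((close & same).sum())
        pair_far_sync = int((~close & same).sum())

    return SpatialSummary(
        n_events=n,
        n_localized=n_loc,
        localized_fraction=_pct(n_loc, n),
        n_synchronized_localized=n_sync_loc,
        n_synchronized_diffuse=n_sync_dif,
        sync_fraction_localized=_pct(n_sync_loc, n_loc),
        sync_fraction_diffuse=_pct(n_sync_dif, n_dif),
        pair_sync_fraction_close=_pct(pair_close_sync, pair_close),
        pair_sync_fraction_far=_pct(pair_far_sync, pair_far),
        radius_um=float(radius),
        sync_window_frames=int(sync_window),
    )
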