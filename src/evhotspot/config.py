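"""Run configuration: every tunable analysis parameter, serializable to YAML.

The resolved configuration (and a short hash of its analysis parameters) is
embedded in every output file so any table can be traced back to the exact
settings that produced it.  Input/output paths are excluded from the hash —
the same analysis on the same data yields the same hash wherever it is
written.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import EventParams


class ConfigError(ValueError):
    """Invalid or unknown configuration input (CLI exit code 2)."""


_PATH_FIELDS = ("movie", "out_dir")


@dataclass
class RunConfig:
    """All pipeline parameters plus I/O paths and the provenance seed."""

    # io
    movie: str | None = None
    out_dir: str | None = None
    seed: int = 0
    # detection
    convert_8bit: bool = False
    gap: int = 1
    threshold: float | str = "auto"
    k_mad: float = 5.0
    min_area: int = 4
    max_area: int = 200
    merge_radius_px: float = 2.0
    # event profiling / QC / classification
    roi_radius_px: int = 4
    baseline_window: int = 10
    k_snr: float = 3.0
    d_max_um: float = 0.5
    r2_min: float = 0.8
    stay_frac: float = 0.7
    end_window: int = 5
    smooth_window: int = 3
    # spatial statistics
    radius_um: float = 5.0
    sync_window: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**d)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc
        if not isinstance(cfg.threshold, str):
            cfg.threshold = float(cfg.threshold)
        elif cfg.threshold != "auto":
            raise ConfigError(f"threshold must be a number or 'auto', got {cfg.threshold!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def params_dict(self) -> dict:
        """Analysis parameters only (no paths) — the hashed provenance record."""
        d = self.to_dict()
        for k in _PATH_FIELDS:
            d.pop(k, None)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.params_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def event_params(self) -> EventParams:
        return EventParams(
            roi_radius_px=self.roi_radius_px,
            baseline_window=self.baseline_window,
            k_snr=self.k_snr,
            d_max_um=self.d_max_um,
            r2_min=self.r2_min,
            stay_frac=self.stay_frac,
            end_window=self.end_window,
            smooth_window=self.smooth_window,
        )
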