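"""Reading and writing movies, sidecars and result tables.

Movies travel as multi-page single-channel TIFF with a JSON sidecar carrying
the physical calibration (``pixel_size_um``, ``frame_interval_s``); result
tables are plain CSV/JSON.  Every table written by the pipeline starts with
a provenance comment line naming the config hash and resolved parameters.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM, MovieStack


class DataError(RuntimeError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


def _sidecar_path(movie_path: Path) -> Path:
    return movie_path.with_suffix(".json")


def write_movie(movie: MovieStack, path: str | Path, extra: dict | None = None) -> Path:
    """Write a movie as uint16 (or uint8) multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    if movie.bit_depth == 8:
        arr = np.clip(np.rint(movie.data), 0, 255).astype(np.uint8)
    else:
        arr = np.clip(np.rint(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "bit_depth": movie.bit_depth,
        "frames": movie.n_frames,
    }
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a multi-page TIFF and its JSON sidecar into a MovieStack.

    A missing sidecar falls back to the default calibration (0.1067 um/px,
    2.5 s/frame) with a prominent warning; a sidecar whose frame count
    disagrees with the TIFF is an error.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise DataError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"movie {path} must be a single-channel T x H x W stack")

    sidecar = _sidecar_path(path)
    pixel_size = DEFAULT_PIXEL_SIZE_UM
    frame_interval = DEFAULT_FRAME_INTERVAL_S
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
        frame_interval = float(meta.get("frame_interval_s", frame_interval))
        bit_depth = int(meta.get("bit_depth", bit_depth))
        if "frames" in meta and int(meta["frames"]) != arr.shape[0]:
            raise DataError(
                f"sidecar frame count {meta['frames']} != TIFF frames {arr.shape[0]}"
            )
    else:
        warnings.warn(
            f"no sidecar {sidecar.name}: assuming defaults "
            f"{DEFAULT_PIXEL_SIZE_UM} um/px and {DEFAULT_FRAME_INTERVAL_S} s/frame",
            stacklevel=2,
        )
    return MovieStack(
        arr.astype(np.float64),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        bit_depth=bit_depth,
    )


def _provenance_line(config_hash: str, params: dict) -> str:
    return f"# evhotspot config_hash={config_hash} params={json.dumps(params, sort_keys=True)}\n"


def write_table(
    df: pd.DataFrame, path: str | Path, config_hash: str = "", params: dict | None = None
) -> Path:
    """CSV with a leading provenance comment line (readable via comment='#')."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(_provenance_line(config_hash, params or {}))
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return path
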