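"""Non-TIRF quantifications: NFAT N/C ratio, bead-panel normalization, growth.

* Nuclear-translocation readout: per cell, mean nuclear intensity divided by
  mean cytoplasmic intensity (N/C ratio), from an image plus label masks.
  Segmentation is out of scope — masks are supplied by the user or by
  :func:`evhotspot.simulate.simulate_nfat_image`.
* Multiplex bead panel (37 capture markers + 2 isotype controls): raw mean
  fluorescence minus the PBS blank, then divided by the mean adjusted signal
  of the tetraspanins CD63, CD81 and CD9.
* Relative growth: percent difference in total cell number of each treatment
  against a reference (vehicle-treated control EVs).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TETRASPANINS = ("CD63", "CD81", "CD9")

#: capture-bead populations of the 37-marker EV surface panel
MACSPLEX_MARKERS = [
    "CD1c", "CD2", "CD3", "CD4", "CD8", "CD9", "CD11c", "CD14", "CD19",
    "CD20", "CD24", "CD25", "CD29", "CD31", "CD40", "CD41b", "CD42a",
    "CD44", "CD45", "CD49e", "CD56", "CD62P", "CD63", "CD69", "CD81",
    "CD86", "CD105", "CD133/1", "CD142", "CD146", "CD209", "CD326",
    "HLA-ABC", "HLA-DR", "MCSP", "ROR1", "SSEA-4",
]
MACSPLEX_ISOTYPES = ["mIgG1", "REA"]


@dataclass
class NfatCellMeasure:
    cell_id: int
    nuclear_mean: float
    cytoplasmic_mean: float
    nc_ratio: float


def nfat_nc_ratio(
    image: np.ndarray,
    nucleus_labels: np.ndarray,
    cytoplasm_labels: np.ndarray,
) -> pd.DataFrame:
    """Per-cell N/C ratio from an intensity image and two label masks.

    Labels number cells 1..n in both masks; the cytoplasm mask is the cell
    minus its nucleus, so the compartments are disjoint.  Cells with an
    empty compartment or non-positive cytoplasmic mean are dropped with a
    logged reason.  The ratio is scale-invariant: multiplying the image by
    a positive constant leaves it unchanged.
    """
    image = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_labels)
    cyt = np.asarray(cytoplasm_labels)
    if image.shape != nuc.shape or image.shape != cyt.shape:
        raise ValueError("image and label masks must share a shape")
    if np.any((nuc > 0) & (cyt > 0)):
        raise ValueError("nucleus and cytoplasm masks must be disjoint")

    ids = sorted(set(np.unique(nuc[nuc > 0])) | set(np.unique(cyt[cyt > 0])))
    rows = []
    for cid in ids:
        nmask = nuc == cid
        cmask = cyt == cid
        if not nmask.any() or not cmask.any():
            logger.warning("cell %d dropped: empty compartment mask", cid)
            continue
        nmean = float(image[nmask].mean())
        cmean = float(image[cmask].mean())
        if cmean <= 0:
            logger.warning("cell %d dropped: non-positive cytoplasmic mean", cid)
            continue
        rows.append(
            {
                "cell_id": int(cid),
                "nuclear_mean": nmean,
                "cytoplasmic_mean": cmean,
                "nc_ratio": nmean / cmean,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "nuclear_mean", "cytoplasmic_mean", "nc_ratio"])


def nfat_batch_summary(measures: pd.DataFrame) -> dict:
    """Batch mean +/- SEM of the N/C ratio across cells."""
    r = measures["nc_ratio"].to_numpy(dtype=float)
    n = r.size
    return {
        "n_cells": int(n),
        "mean_nc_ratio": float(r.mean()) if n else float("nan"),
        "sem_nc_ratio": float(r.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }


def normalize_macsplex(panel: pd.DataFrame) -> pd.DataFrame:
    """Blank-adjust and tetraspanin-normalize a bead-panel intensity table.

    ``panel`` must carry one row per marker (indexed by marker name, or with
    a ``marker`` column) and columns ``raw_intensity`` and
    ``pbs_control_intensity``.  Adds ``adjusted = raw - pbs`` and
    ``normalized = adjusted / mean(adjusted over CD63, CD81, CD9)``.  The
    operation is invariant to a common additive offset on raw and PBS, and
    idempotent on the adjusted field.
    """
    df = panel.copy()
    if "marker" in df.columns:
        df = df.set_index("marker")
    missing = [m for m in TETRASPANINS if m not in df.index]
    if missing:
        raise ValueError(f"tetraspanin marker(s) missing from panel: {missing}")
    for col in ("raw_intensity", "pbs_control_intensity"):
        if col not in df.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    df["adjusted"] = df["raw_intensity"] - df["pbs_control_intensity"]
    tetra_mean = float(df.loc[list(TETRASPANINS), "adjusted"].mean())
    if tetra_mean <= 0:
        raise ValueError(
            f"cannot normalize: mean adjusted tetraspanin signal is {tetra_mean:.3g} (<= 0)"
        )
    df["normalized"] = df["adjusted"] / tetra_mean
    return df


def example_panel(seed: int = 0) -> pd.DataFrame:
    """Synthetic bead-panel table with plausible signal structure (for demos/tests)."""
    rng = np.random.default_rng(seed)
    markers = MACSPLEX_MARKERS + MACSPLEX_ISOTYPES
    pbs = rng.uniform(20.0, 60.0, size=len(markers))
    raw = pbs + rng.exponential(30.0, size=len(markers))
    df = pd.DataFrame(
        {"marker": markers, "raw_intensity": raw, "pbs_control_intensity": pbs}
    )
    # tetraspanins dominate an EV prep; isotype controls sit at blank level
    for m in TETRASPANINS:
        df.loc[df["marker"] == m, "raw_intensity"] = df.loc[
            df["marker"] == m, "pbs_control_intensity"
        ] + rng.uniform(800.0, 1500.0)
    for m in MACSPLEX_ISOTYPES:
        df.loc[df["marker"] == m, "raw_intensity"] = df.loc[
            df["marker"] == m, "pbs_control_intensity"
        ]
    return df


def relative_growth(counts: pd.Series | dict, reference: str = "DMSO-EV") -> pd.Series:
    """Percent difference in cell number of each treatment vs the reference.

    ``100 * (count - reference_count) / reference_count`` per treatment;
    the reference itself maps to 0.
    """
    s = pd.Series(counts, dtype=float)
    if reference not in s.index:
        raise ValueError(f"reference treatment {reference!r} missing from counts")
    ref = float(s[reference])
    if ref <= 0:
        raise ValueError("reference count must be positive")
    return 100.0 * (s - ref) / ref
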