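"""Mask-based single-cell quantification and gating.

Inputs are a single-channel fluorescence image plus integer-labelled rasters
(0 = background): one for whole-cell masks, optionally one for DNA masks.
Coordinates are row-major, 0-based pixel indices; distances are measured
between pixel centres (so a single pixel has Feret diameter 0 — no
corner-to-corner +1 correction, unlike some toolkits).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .params import GateConfig

logger = logging.getLogger(__name__)


def feret_diameter(mask) -> float:
    """Longest pixel-centre-to-pixel-centre distance within a mask.

    ``mask`` is a 2D boolean array or an (N, 2) array of pixel coordinates.
    The maximum is taken over the convex hull of the pixel centres, which
    equals the brute-force all-pairs maximum; degenerate (collinear or
    single-pixel) masks fall back to the direct computation.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2 and mask.dtype != bool and mask.shape[1] != 2:
        mask = mask > 0
    pts = np.argwhere(mask).astype(float) if mask.dtype == bool else mask.astype(float)
    if pts.size == 0:
        raise ValueError("feret_diameter: empty mask")
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: all-pairs on the raw set is still cheap
    return float(pdist(pts).max())


def px_to_um(length_px: float, px_per_um: float = 15.3609) -> float:
    """Convert a pixel length to micrometres using the image scale."""
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    return float(length_px) / float(px_per_um)


def quantify(image: np.ndarray, cell_masks: np.ndarray) -> pd.DataFrame:
    """Per-label intensity statistics under each cell mask.

    Returns one row per positive label present in ``cell_masks`` with
    columns label, area_px, total, mean, median, max, length_px (Feret
    diameter of the mask).
    """
    image = np.asarray(image, dtype=float)
    cell_masks = np.asarray(cell_masks)
    if image.shape != cell_masks.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs masks {cell_masks.shape}"
        )
    labels = cell_masks.ravel()
    vals = image.ravel()
    sel = labels > 0
    df = pd.DataFrame({"label": labels[sel], "value": vals[sel]})
    if df.empty:
        raise ValueError("quantify: no labelled pixels")
    stats = (
        df.groupby("label")["value"]
        .agg(area_px="size", total="sum", mean="mean", median="median", max="max")
        .reset_index()
    )
    ferets = {
        int(lab): feret_diameter(cell_masks == lab) for lab in stats["label"].astype(int)
    }
    stats["length_px"] = stats["label"].astype(int).map(ferets)
    stats["label"] = stats["label"].astype(int)
    return stats


def count_nuclei(
    cell_masks: np.ndarray, dna_masks: np.ndarray
) -> tuple[pd.DataFrame, list[int]]:
    """Nucleus count per cell by majority overlap of DNA components.

    A DNA component is assigned to the cell mask containing the strict
    majority (>50%) of its pixels; ties and components with no majority
    cell are left unassigned and logged. Returns (DataFrame with columns
    label, n_nuclei — one row per cell label — and the list of unassigned
    DNA labels).
    """
    cell_masks = np.asarray(cell_masks)
    dna_masks = np.asarray(dna_masks)
    if cell_masks.shape != dna_masks.shape:
        raise ValueError("cell and DNA masks must share the same geometry")
    cell_labels = np.unique(cell_masks[cell_masks > 0])
    counts = {int(lab): 0 for lab in cell_labels}
    unassigned: list[int] = []
    for dna_lab in np.unique(dna_masks[dna_masks > 0]):
        under = cell_masks[dna_masks == dna_lab]
        npix = under.size
        owners, freq = np.unique(under[under > 0], return_counts=True)
        if len(owners) == 0 or freq.max() * 2 <= npix:
            unassigned.append(int(dna_lab))
            continue
        top = freq == freq.max()
        if top.sum() > 1:
            unassigned.append(int(dna_lab))
            continue
        counts[int(owners[np.argmax(freq)])] += 1
    if unassigned:
        logger.info("count_nuclei: %d unassigned DNA component(s): %s", len(unassigned), unassigned)
    return (
        pd.DataFrame(
            {"label": list(counts.keys()), "n_nuclei": list(counts.values())}
        ).sort_values("label", ignore_index=True),
        unassigned,
    )


def gate_cells(table: pd.DataFrame, gates: Optional[GateConfig] = None) -> pd.DataFrame:
    """Apply post-acquisition gates; returns a filtered copy.

    Enabled gates: the mononucleate filter (``n_nuclei == 1``) and interval
    gates on ``thickness_px`` / ``width_px`` / any column listed in
    ``gates.extra_gates``. A missing feature column for an enabled gate is
    an error; removal counts per gate are logged. Gating is idempotent.
    """
    gates = gates or GateConfig()
    keep = pd.Series(True, index=table.index)
    removed: dict[str, int] = {}

    def apply(name: str, col: str, lo, hi) -> None:
        nonlocal keep
        if lo is None and hi is None:
            return
        if col not in table.columns:
            raise ValueError(f"gate {name!r} enabled but column {col!r} missing")
        ok = pd.Series(True, index=table.index)
        if lo is not None:
            ok &= table[col] >= lo
        if hi is not None:
            ok &= table[col] <= hi
        removed[name] = int((keep & ~ok).sum())
        keep &= ok

    if gates.require_mononucleate:
        if "n_nuclei" not in table.columns:
            raise ValueError("mononucleate gate enabled but n_nuclei column missing")
        ok = table["n_nuclei"] == 1
        removed["mononucleate"] = int((keep & ~ok).sum())
        keep &= ok
    apply("thickness", "thickness_px", gates.thickness_min_px, gates.thickness_max_px)
    apply("width", "width_px", None, gates.width_max_px)
    for col, (lo, hi) in gates.extra_gates.items():
        apply(col, col, lo, hi)

    if removed:
        logger.info("gate_cells: removals per gate: %s", removed)
    return table[keep].copy()


def quantify_to_cell_table(
    image: np.ndarray,
    cell_masks: np.ndarray,
    dna_masks: Optional[np.ndarray] = None,
    px_per_um: float = 15.3609,
    channel: str = "HPG",
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Quantify an image into the standard cell-table format.

    Combines :func:`quantify`, :func:`count_nuclei` and :func:`px_to_um`
    into one table with the simulator's column layout, so quantified images
    and simulated tables flow through the same downstream pipeline.
    """
    stats = quantify(image, cell_masks)
    if dna_masks is not None:
        nuclei, _ = count_nuclei(cell_masks, dna_masks)
        stats = stats.merge(nuclei, on="label", how="left")
        stats["n_nuclei"] = stats["n_nuclei"].fillna(0).astype(int)
    else:
        stats["n_nuclei"] = 1
    out = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}:m{int(l):04d}" for l in stats["label"]],
            "sample_id": sample_id,
            "strain_id": "unknown",
            "replicate": 1,
            "length_um": [px_to_um(l, px_per_um) for l in stats["length_px"]],
            "area_px": stats["area_px"].astype(int),
            "n_nuclei": stats["n_nuclei"],
            "is_background": False,
            f"signal_{channel}": stats["total"],
        }
    )
    for ch in ("HPG", "AHA"):
        if f"signal_{ch}" not in out.columns:
            out[f"signal_{ch}"] = np.nan
    return out
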