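"""Background correction, length binning, and signal normalization.

The correction pipeline mirrors the assay's processing order:

1. :func:`background_scale` — divide every total signal by the median total
   signal of the background sample (cells fixed immediately after analogue
   addition), putting all experiments on a common scale.
2. :func:`background_subtract_binned` — group cells in 1-µm length bins and
   subtract, per bin, the median scaled background signal; the result is the
   per-cell incorporation estimate.

Two further normalizations serve different figures of merit:
:func:`length_normalize_ols` divides each observed signal by the value an OLS
regression on length predicts for that cell, and
:func:`per_length_median_normalize` divides signal by length and rescales to a
population median of one.

All functions return a copy with new columns appended
(``signal_{ch}_scaled``, ``signal_{ch}_corr``, ``signal_{ch}_lennorm``,
``signal_{ch}_norm``); inputs are never mutated.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .params import LengthBinning

logger = logging.getLogger(__name__)


def _signal_col(table: pd.DataFrame, channel: str, col: Optional[str]) -> str:
    col = col or f"signal_{channel}"
    if col not in table.columns:
        raise ValueError(f"missing signal column {col!r}")
    return col


def _background_mask(table: pd.DataFrame) -> pd.Series:
    if "is_background" not in table.columns:
        raise ValueError("table has no is_background column")
    return table["is_background"].astype(bool)


def assign_length_bins(
    table: pd.DataFrame, binning: Optional[LengthBinning] = None
) -> pd.DataFrame:
    """Assign each cell to a half-open length bin [k·w, (k+1)·w).

    Bin edges sit at integer multiples of the width; the ``bin_centre_um``
    column holds the bin centre. Every row maps to exactly one bin, so the
    row count is preserved.
    """
    binning = binning or LengthBinning()
    if "length_um" not in table.columns:
        raise ValueError("table has no length_um column")
    lengths = table["length_um"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    w = binning.width_um
    idx = np.floor(lengths / w).astype(int)
    out = table.copy()
    out["bin_centre_um"] = (idx + 0.5) * w
    return out


def background_scale(
    table: pd.DataFrame, channel: str = "HPG", signal_col: Optional[str] = None
) -> pd.DataFrame:
    """Divide total signals by the median background-sample total signal.

    Applied to sample and background rows alike, so the scaled background
    sample can feed :func:`background_subtract_binned` directly.
    """
    col = _signal_col(table, channel, signal_col)
    bg = _background_mask(table)
    bg_vals = table.loc[bg, col].dropna()
    if bg_vals.empty:
        raise ValueError("background sample is empty")
    med = float(bg_vals.median())
    if med <= 0:
        raise ValueError(f"nonpositive background median {med:.4g}")
    out = table.copy()
    out[f"signal_{channel}_scaled"] = out[col] / med
    return out


def background_subtract_binned(
    table: pd.DataFrame,
    channel: str = "HPG",
    binning: Optional[LengthBinning] = None,
    signal_col: Optional[str] = None,
) -> pd.DataFrame:
    """Subtract the per-length-bin median background from each cell's signal.

    Expects already background-scaled signals (``signal_{ch}_scaled``).
    Bins that contain no background cells fall back to the global background
    median (logged). Negative corrected values are retained: downstream
    quantile statistics tolerate them, and clipping would bias low signals.
    """
    binning = binning or LengthBinning()
    col = signal_col or f"signal_{channel}_scaled"
    if col not in table.columns:
        raise ValueError(
            f"missing column {col!r}; run background_scale first or pass signal_col"
        )
    bg = _background_mask(table)
    if not bg.any():
        raise ValueError("background sample is empty")

    binned = table if "bin_centre_um" in table.columns else assign_length_bins(table, binning)
    global_med = float(binned.loc[bg, col].median())
    per_bin = binned.loc[bg].groupby("bin_centre_um")[col].median()

    centres = binned["bin_centre_um"]
    med_for_cell = centres.map(per_bin)
    missing = med_for_cell.isna()
    if missing.any():
        n_bins = binned.loc[missing, "bin_centre_um"].nunique()
        logger.info(
            "background_subtract_binned: %d bin(s) without background cells; "
            "falling back to global background median %.4g",
            n_bins,
            global_med,
        )
        med_for_cell = med_for_cell.fillna(global_med)

    out = binned.copy()
    out[f"signal_{channel}_corr"] = out[col] - med_for_cell
    return out


def length_normalize_ols(
    table: pd.DataFrame, channel: str = "HPG", signal_col: Optional[str] = None
) -> pd.DataFrame:
    """Divide each signal by its OLS-predicted value at the cell's length.

    An unweighted OLS regression of signal on length (intercept included) is
    fitted on the non-background cells; each cell's observed signal is then
    divided by the fitted prediction. Cells with a nonpositive prediction are
    flagged (``signal_{ch}_lennorm`` set to NaN) and logged, so downstream
    statistics skip them.
    """
    col = _signal_col(table, channel, signal_col)
    bg = _background_mask(table) if "is_background" in table.columns else pd.Series(
        False, index=table.index
    )
    sub = table.loc[~bg, ["length_um", col]].dropna()
    if len(sub) < 3:
        raise ValueError("length_normalize_ols: need at least 3 cells")
    x = sub["length_um"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("length_normalize_ols: zero length variance")
    slope, intercept = np.polyfit(x, y, 1)

    out = table.copy()
    pred = intercept + slope * out["length_um"]
    norm = out[col] / pred
    bad = (~bg) & (pred <= 0) & out[col].notna()
    if bad.any():
        logger.warning(
            "length_normalize_ols: %d cell(s) with nonpositive predicted signal "
            "flagged and excluded",
            int(bad.sum()),
        )
        norm[bad] = np.nan
    norm[bg] = np.nan
    out[f"signal_{channel}_lennorm"] = norm
    out.attrs[f"lennorm_{channel}_fit"] = {"slope": float(slope), "intercept": float(intercept)}
    return out


def per_length_median_normalize(
    table: pd.DataFrame, channel: str = "HPG", signal_col: Optional[str] = None
) -> pd.DataFrame:
    """Signal divided by cell length, rescaled to population median one.

    The median is taken over non-background cells; the output column
    ``signal_{ch}_norm`` has population median exactly 1 by construction.
    """
    col = _signal_col(table, channel, signal_col)
    bg = _background_mask(table) if "is_background" in table.columns else pd.Series(
        False, index=table.index
    )
    per_len = table[col] / table["length_um"]
    med = float(per_len[~bg].dropna().median())
    if not np.isfinite(med) or med <= 0:
        raise ValueError(f"per_length_median_normalize: invalid population median {med!r}")
    out = table.copy()
    norm = per_len / med
    norm[bg] = np.nan
    out[f"signal_{channel}_norm"] = norm
    return out
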