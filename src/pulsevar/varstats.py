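"""Variability statistics: quantiles, QCD, CV, and per-length-bin profiles.

The quartile coefficient of dispersion, QCD = (Q3 − Q1)/(Q3 + Q1), is the
headline dispersion measure: it is invariant under positive rescaling and,
unlike the CV, insensitive to the extreme upper tail of a long-tailed
single-cell signal distribution.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .params import LengthBinning, VariabilitySummary

logger = logging.getLogger(__name__)


def quantiles(values, p: float) -> float:
    """Quantile by linear interpolation of order statistics (h = (n−1)p + 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantiles: empty input")
    if not 0.0 <= p <= 1.0:
        raise ValueError("quantiles: p must lie in [0, 1]")
    return float(np.quantile(values, p))


def qcd(values) -> float:
    """Quartile coefficient of dispersion (Q3 − Q1)/(Q3 + Q1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("qcd: need at least 4 values")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    denom = q3 + q1
    if denom <= 0:
        raise ValueError(
            f"qcd undefined: q1 + q3 = {denom:.4g} <= 0 (q1={q1:.4g}, q3={q3:.4g})"
        )
    return float((q3 - q1) / denom)


def cv(values) -> float:
    """Coefficient of variation: sample SD (n−1 denominator) over mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("cv: need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError(f"cv undefined: mean = {mean:.4g} <= 0")
    return float(values.std(ddof=1) / mean)


def summarize(values) -> VariabilitySummary:
    """Full variability summary (quartiles, QCD, CV, mean, SD) of one vector."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("summarize: need at least 4 values")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return VariabilitySummary(
        n=int(values.size),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        qcd=float((q3 - q1) / (q3 + q1)) if (q3 + q1) > 0 else float("nan"),
        cv=sd / mean if mean > 0 else float("nan"),
        mean=mean,
        sd=sd,
    )


def bin_variability_profile(
    table: pd.DataFrame,
    channel: str = "HPG",
    binning: Optional[LengthBinning] = None,
    min_n: int = 50,
    signal_col: Optional[str] = None,
) -> pd.DataFrame:
    """Per-length-bin variability summaries of a binned cell table.

    Parameters
    ----------
    table
        Cell table carrying a ``bin_centre_um`` column (see
        :func:`pulsevar.normalize.assign_length_bins`) or a ``length_um``
        column (bins are then assigned on the fly).
    channel
        Label channel; the default signal column is ``signal_{channel}_corr``
        if present, else ``signal_{channel}``.
    min_n
        Bins with fewer cells are reported in the log but not summarized.

    Returns
    -------
    DataFrame with columns bin_centre_um, n, q1, q2, q3, qcd, cv, mean, sd,
    p2_5, p97_5 — one row per bin with at least ``min_n`` cells.
    """
    if min_n < 4:
        raise ValueError("bin_variability_profile: min_n must be >= 4")
    if signal_col is None:
        corr = f"signal_{channel}_corr"
        signal_col = corr if corr in table.columns else f"signal_{channel}"
    if signal_col not in table.columns:
        raise ValueError(f"missing signal column {signal_col!r}")
    if "bin_centre_um" not in table.columns:
        from .normalize import assign_length_bins

        table = assign_length_bins(table, binning or LengthBinning())

    rows = []
    skipped = []
    for centre, grp in table.groupby("bin_centre_um", sort=True):
        vals = grp[signal_col].dropna().to_numpy()
        if vals.size < min_n:
            skipped.append((centre, vals.size))
            continue
        s = summarize(vals)
        p_lo, p_hi = np.quantile(vals, [0.025, 0.975])
        rows.append(
            {
                "bin_centre_um": centre,
                "n": s.n,
                "q1": s.q1,
                "q2": s.q2,
                "q3": s.q3,
                "qcd": s.qcd,
                "cv": s.cv,
                "mean": s.mean,
                "sd": s.sd,
                "p2_5": float(p_lo),
                "p97_5": float(p_hi),
            }
        )
    if skipped:
        logger.info(
            "bin_variability_profile: %d bin(s) below min_n=%d not summarized: %s",
            len(skipped),
            min_n,
            skipped,
        )
    if not rows:
        raise ValueError(f"no length bin reaches min_n={min_n} cells")
    return pd.DataFrame(rows)
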