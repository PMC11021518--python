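"""Replicate-thresholded QCD variability screen.

Each strain's per-replicate QCD is compared against the mean ± k·SD band of
the wild-type replicate QCDs (k = 1.5 by default): strains above the band
are flagged ``high``, below ``low``. No multiple-testing correction is
applied by default, matching the screen's design; a Benjamini–Hochberg
helper is available for the pairwise tests.

The pairwise replicate comparison is a two-sided paired t-test on the
per-replicate QCD differences. The protocol names this a "Welch's unequal
variances paired t test", which is internally contradictory — the Welch
correction applies to unpaired samples — so the paired t on differences is
the default and an unpaired Welch variant sits behind ``method="welch"``;
the ambiguity is logged once per call.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import normalize, varstats

logger = logging.getLogger(__name__)


def strain_qcd_table(
    table: pd.DataFrame,
    mode: str = "mean_signal",
    channel: str = "HPG",
    min_cells: int = 100,
) -> pd.DataFrame:
    """Per-strain, per-replicate QCD of the chosen signal convention.

    ``mode="mean_signal"``: QCD of the per-cell mean signal (total signal
    over mask area) divided by the sample median — the imaging-flow-cytometry
    convention; background is not subtracted, and the median division leaves
    QCD unchanged (scale invariance) but puts samples on a common scale.

    ``mode="length_normalized"``: QCD of the OLS length-normalized raw
    signal (background not subtracted) — the microscopy convention.

    Samples with fewer than ``min_cells`` usable cells are excluded with a
    warning. Returns columns strain_id, replicate, qcd, n.
    """
    if mode not in ("mean_signal", "length_normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    sig = f"signal_{channel}"
    if sig not in table.columns:
        raise ValueError(f"missing column {sig!r}")
    cells = table
    if "is_background" in cells.columns:
        cells = cells[~cells["is_background"].astype(bool)]

    rows = []
    for (strain_id, rep), grp in cells.groupby(["strain_id", "replicate"], sort=True):
        if mode == "mean_signal":
            denom = grp["area_px"] if "area_px" in grp.columns else grp["length_um"]
            vals = (grp[sig] / denom).dropna()
            vals = vals / vals.median()
        else:
            norm = normalize.length_normalize_ols(grp, channel)
            vals = norm[f"signal_{channel}_lennorm"].dropna()
        if len(vals) < min_cells:
            logger.warning(
                "strain_qcd_table: sample %s replicate %s has %d < %d cells; excluded",
                strain_id,
                rep,
                len(vals),
                min_cells,
            )
            continue
        rows.append(
            {
                "strain_id": strain_id,
                "replicate": rep,
                "qcd": varstats.qcd(vals.to_numpy()),
                "n": len(vals),
            }
        )
    if not rows:
        raise ValueError("no sample reaches min_cells")
    return pd.DataFrame(rows)


def flag_variability(
    qcd_table: pd.DataFrame,
    wildtype: str = "WT",
    k: float = 1.5,
) -> pd.DataFrame:
    """Flag strains whose mean QCD leaves the wild-type mean ± k·SD band.

    ``qcd_table`` is the output of :func:`strain_qcd_table`. Thresholds use
    the sample SD (n−1) of the wild-type replicate QCDs, which requires at
    least two wild-type replicates. Returns one row per strain with the
    replicate QCDs, their mean and SD, the wild-type band, and the flag
    (``high`` / ``low`` / ``none``).
    """
    wt = qcd_table[qcd_table["strain_id"] == wildtype]["qcd"].to_numpy(dtype=float)
    if len(wt) < 2:
        raise ValueError(
            f"need >= 2 wild-type ({wildtype!r}) replicates to define the band"
        )
    wt_mean = float(wt.mean())
    wt_sd = float(wt.std(ddof=1))
    hi, lo = wt_mean + k * wt_sd, wt_mean - k * wt_sd

    rows = []
    for strain_id, grp in qcd_table.groupby("strain_id", sort=True):
        q = grp["qcd"].to_numpy(dtype=float)
        q_mean = float(q.mean())
        flag = "high" if q_mean > hi else ("low" if q_mean < lo else "none")
        rows.append(
            {
                "strain_id": strain_id,
                "n_replicates": len(q),
                "qcd_per_replicate": list(np.round(q, 6)),
                "qcd_mean": q_mean,
                "qcd_sd": float(q.std(ddof=1)) if len(q) > 1 else 0.0,
                "wt_mean": wt_mean,
                "wt_sd": wt_sd,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def paired_difference_test(
    qcd_a: Sequence[float],
    qcd_b: Sequence[float],
    method: str = "paired",
) -> tuple[float, float, float]:
    """Two-sided test on replicate-matched QCDs; returns (t, p, df).

    ``method="paired"`` (default): t-test on the per-replicate differences.
    ``method="welch"``: unpaired Welch unequal-variances variant, provided
    because the protocol's naming conflates the two.

    Zero-variance differences are degenerate: the statistic is ±inf and
    p = 0, reported with a warning rather than an error.
    """
    a = np.asarray(qcd_a, dtype=float)
    b = np.asarray(qcd_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal replicate counts >= 2, replicate-matched")
    logger.info(
        "paired_difference_test: using %s t-test (the protocol's 'Welch's "
        "paired t test' is ambiguous; Welch applies to unpaired samples)",
        method,
    )
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue), float(res.df)
    if method != "paired":
        raise ValueError(f"unknown method {method!r}")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    df = float(n - 1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, df
        logger.warning(
            "paired_difference_test: zero-variance nonzero differences; "
            "degenerate t = ±inf, p = 0"
        )
        return math.copysign(float("inf"), d.mean()), 0.0, df
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, df


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the screen applies none by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def run_screen(
    table: pd.DataFrame,
    wildtype: str = "WT",
    k: float = 1.5,
    mode: str = "mean_signal",
    channel: str = "HPG",
    min_cells: int = 100,
    wt_comparisons: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screen: per-replicate QCDs, flags, and optional pairwise tests.

    ``wt_comparisons`` lists strain_ids to compare against the wild type
    with :func:`paired_difference_test` (replicate-matched); pass None to
    skip. Returns (screen table, pairwise-test table).
    """
    qcds = strain_qcd_table(table, mode=mode, channel=channel, min_cells=min_cells)
    flags = flag_variability(qcds, wildtype=wildtype, k=k)
    tests = []
    for strain_id in wt_comparisons or []:
        a = qcds[qcds["strain_id"] == strain_id].sort_values("replicate")["qcd"]
        b = qcds[qcds["strain_id"] == wildtype].sort_values("replicate")["qcd"]
        if len(a) != len(b):
            raise ValueError(
                f"{strain_id}: replicate count {len(a)} does not match wild type {len(b)}"
            )
        t, p, df = paired_difference_test(a.to_numpy(), b.to_numpy())
        tests.append({"strain_id": strain_id, "t": t, "p": p, "df": df})
    return flags, pd.DataFrame(tests)
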