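"""Dual-label decorrelation analysis.

Two sequential pulses with distinct labels (HPG then AHA) measure the same
cell's synthesis rate at two times. The squared correlation (OLS R²) between
the per-length median-normalized channel signals, as a function of the
interval between pulses, traces how quickly single-cell rates decorrelate.
The decay is summarized by fitting

    R²(Δt) = r2_0 · exp(−2 (Δt/τ)^β)

(the square of a stretched-exponential correlation, attenuated by an
interval-independent factor r2_0 from channel noise) and reporting the
half-decay interval t½ = τ (ln2 / 2)^{1/β}.

Ranked-group trajectories quantify regression to the mean: cells are split
into deciles of their first-pulse signal, and each decile's mean normalized
second-pulse signal is followed as the interval grows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import DecorrelationFit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r2: float


def ols_fit(x, y) -> OLSFit:
    """Closed-form ordinary least squares of y on x with R² = 1 − SSE/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("ols_fit: need at least 3 finite points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("ols_fit: degenerate x (zero variance)")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return OLSFit(slope=slope, intercept=intercept, r2=r2)


def _as_interval_map(
    samples: Mapping[float, pd.DataFrame] | pd.DataFrame,
) -> dict[float, pd.DataFrame]:
    if isinstance(samples, pd.DataFrame):
        if "interval_min" not in samples.columns:
            raise ValueError("single-table input needs an interval_min column")
        return {
            float(iv): grp for iv, grp in samples.groupby("interval_min", sort=True)
        }
    return {float(k): v for k, v in sorted(samples.items())}


def r2_decay_curve(
    samples: Mapping[float, pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-interval OLS R² of normalized AHA on normalized HPG.

    Each sample must carry ``signal_HPG_norm`` and ``signal_AHA_norm``
    columns (per-length median-normalized signals). Returns a frame with
    columns interval_min, r2, n in interval order.
    """
    rows = []
    for interval, df in _as_interval_map(samples).items():
        for col in ("signal_HPG_norm", "signal_AHA_norm"):
            if col not in df.columns:
                raise ValueError(f"interval {interval:g}: missing column {col!r}")
        sub = df[["signal_HPG_norm", "signal_AHA_norm"]].dropna()
        fit = ols_fit(sub["signal_HPG_norm"], sub["signal_AHA_norm"])
        rows.append({"interval_min": interval, "r2": fit.r2, "n": len(sub)})
    return pd.DataFrame(rows)


def half_decay_interval(tau: float, beta: float) -> float:
    """Interval at which exp(−2 (t/τ)^β) falls to 1/2."""
    return tau * (0.5 * math.log(2.0)) ** (1.0 / beta)


def fit_decorrelation(curve: pd.DataFrame) -> DecorrelationFit:
    """Fit R²(Δt) = r2_0 · exp(−2 (Δt/τ)^β) to a decay curve.

    ``curve`` needs columns interval_min and r2, with at least three
    intervals including 0. A coarse (τ, β) grid with the optimal r2_0
    solved linearly at each node seeds a bounded local least-squares
    refinement. A non-decreasing curve triggers a warning and the returned
    parameters may sit at the bounds.
    """
    t = curve["interval_min"].to_numpy(dtype=float)
    y = curve["r2"].to_numpy(dtype=float)
    if len(t) < 3 or 0.0 not in t:
        raise ValueError("fit_decorrelation: need >= 3 intervals including 0")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.all(np.diff(y) >= 0):
        logger.warning("fit_decorrelation: R² curve is non-decreasing; fit is suspect")

    def model_weights(tau, beta):
        return np.exp(-2.0 * (t / tau) ** beta)

    best = None
    for tau in np.geomspace(2.0, 500.0, 40):
        for beta in np.linspace(0.2, 2.0, 37):
            w = model_weights(tau, beta)
            denom = float(np.sum(w**2))
            r0 = float(np.clip(np.sum(w * y) / denom, 1e-6, 1.0))
            sse = float(np.sum((y - r0 * w) ** 2))
            if best is None or sse < best[0]:
                best = (sse, tau, beta, r0)
    _, tau0, beta0, r00 = best

    def resid(theta):
        tau, beta, r0 = math.exp(theta[0]), theta[1], theta[2]
        return r0 * model_weights(tau, beta) - y

    sol = least_squares(
        resid,
        x0=[math.log(tau0), beta0, r00],
        bounds=([math.log(0.5), 0.05, 1e-6], [math.log(2000.0), 2.0, 1.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    tau_hat = math.exp(sol.x[0])
    beta_hat = float(sol.x[1])
    r2_0 = float(sol.x[2])
    at_bound = beta_hat >= 1.999 or beta_hat <= 0.051 or tau_hat >= 1999
    if at_bound:
        logger.warning(
            "fit_decorrelation: parameters at bounds (tau=%.3g, beta=%.3g)",
            tau_hat,
            beta_hat,
        )
    return DecorrelationFit(
        r2_0=r2_0,
        tau_hat_min=tau_hat,
        beta_hat=beta_hat,
        half_decay_min=half_decay_interval(tau_hat, beta_hat),
        residual_sse=float(np.sum(sol.fun**2)),
    )


def rank_groups(
    table: pd.DataFrame,
    channel: str = "HPG",
    n_groups: int = 10,
    value_col: Optional[str] = None,
) -> pd.Series:
    """Split cells into ranked groups of the normalized first-pulse signal.

    Cells are sorted ascending by ``signal_{channel}_norm`` (ties broken by
    ``cell_id`` so assignment is deterministic and invariant to input row
    order) and cut into ``n_groups`` contiguous groups whose sizes differ by
    at most one; when the division is uneven the extra cells go to the
    lowest groups. Returns a 1-based group index aligned to the input index.
    """
    value_col = value_col or f"signal_{channel}_norm"
    if value_col not in table.columns:
        raise ValueError(f"missing column {value_col!r}")
    n = len(table)
    if n < n_groups:
        raise ValueError(f"cannot form {n_groups} groups from {n} cells")
    order = np.lexsort(
        (table["cell_id"].to_numpy(), table[value_col].to_numpy(dtype=float))
    )
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = g
        start += size
    return pd.Series(labels, index=table.index, name="group")


def group_trajectories(
    samples: Mapping[float, pd.DataFrame] | pd.DataFrame,
    n_groups: int = 10,
    convergence_fraction: float = 1.0 / 3.0,
    deviation_scale: str = "log",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, float]]:
    """Ranked-group regression-to-the-mean trajectories.

    Within each interval's sample, cells are grouped on normalized HPG and
    each group's mean normalized AHA signal is recorded. The convergence
    time of an extreme group (1 and ``n_groups``) is the earliest interval
    on the grid at which its deviation from that interval's population mean
    first falls below ``convergence_fraction`` of its deviation at interval
    0 (NaN if it never does).

    Deviation is geometric by default (``|log(group mean / population
    mean)|``): the signal is multiplicative, and on the log scale the decay
    of both extreme groups is proportional to the underlying rate
    correlation, whereas the arithmetic deviation of the low group decays
    artificially slowly (concavity of 1 − e^{−x}).
    ``deviation_scale="absolute"`` selects the arithmetic variant.

    Returns (trajectory table, population-mean table, convergence times).
    """
    if deviation_scale not in ("log", "absolute"):
        raise ValueError("deviation_scale must be 'log' or 'absolute'")
    by_interval = _as_interval_map(samples)
    if 0.0 not in by_interval:
        raise ValueError("group_trajectories: need an interval-0 sample")
    traj_rows, pop_rows = [], []
    for interval, df in by_interval.items():
        sub = df.dropna(subset=["signal_HPG_norm", "signal_AHA_norm"])
        if sub.empty:
            raise ValueError(f"interval {interval:g}: no usable cells")
        groups = rank_groups(sub, "HPG", n_groups)
        pop_mean = float(sub["signal_AHA_norm"].mean())
        pop_rows.append({"interval_min": interval, "mean_norm_aha": pop_mean, "n": len(sub)})
        for g, grp in sub.groupby(groups):
            traj_rows.append(
                {
                    "interval_min": interval,
                    "group": int(g),
                    "mean_norm_aha": float(grp["signal_AHA_norm"].mean()),
                    "n": len(grp),
                }
            )
    traj = pd.DataFrame(traj_rows).sort_values(["interval_min", "group"], ignore_index=True)
    pop = pd.DataFrame(pop_rows).sort_values("interval_min", ignore_index=True)

    merged = traj.merge(pop[["interval_min", "mean_norm_aha"]], on="interval_min", suffixes=("", "_pop"))
    if deviation_scale == "log":
        merged["deviation"] = np.abs(
            np.log(merged["mean_norm_aha"] / merged["mean_norm_aha_pop"])
        )
    else:
        merged["deviation"] = (merged["mean_norm_aha"] - merged["mean_norm_aha_pop"]).abs()
    convergence: dict[int, float] = {}
    for g in (1, n_groups):
        dev = merged[merged["group"] == g].set_index("interval_min")["deviation"].sort_index()
        d0 = dev.loc[0.0]
        hit = dev[dev < convergence_fraction * d0]
        convergence[g] = float(hit.index[0]) if len(hit) else float("nan")
    return traj, pop, convergence
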