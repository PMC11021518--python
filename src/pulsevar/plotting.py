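"""Optional plotting helpers (kernel density ridges, decay curves).

These are conveniences for visual inspection only; no statistic in the
package depends on them. Kernel density estimates use Silverman bandwidth.
"""

from __future__ import annotations

import numpy as np


def kde_by_bin(table, channel="HPG", signal_col=None, ax=None):
    """Kernel density estimate of the signal per length bin (Silverman)."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    signal_col = signal_col or f"signal_{channel}_corr"
    if ax is None:
        _, ax = plt.subplots()
    for centre, grp in table.groupby("bin_centre_um"):
        vals = grp[signal_col].dropna().to_numpy()
        if len(vals) < 10:
            continue
        kde = gaussian_kde(vals, bw_method="silverman")
        xs = np.linspace(vals.min(), vals.max(), 200)
        ax.plot(xs, kde(xs), label=f"{centre:g} µm")
    ax.set_xlabel(signal_col)
    ax.set_ylabel("density")
    ax.legend(fontsize="x-small")
    return ax


def plot_decay_curve(curve, fit=None, ax=None):
    """Dual-pulse R² versus interval, with the fitted decay overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["interval_min"], curve["r2"], "o", label="measured")
    if fit is not None:
        ts = np.linspace(0, curve["interval_min"].max(), 200)
        ax.plot(
            ts,
            fit.r2_0 * np.exp(-2.0 * (ts / fit.tau_hat_min) ** fit.beta_hat),
            "-",
            label=f"fit (t½ = {fit.half_decay_min:.1f} min)",
        )
    ax.set_xlabel("interval between pulses (min)")
    ax.set_ylabel("OLS R²")
    ax.legend()
    return ax
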