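"""High-level experiment pipelines composing the simulator with the analyses.

These are the entry points the command-line interface and the reproduction
script call: each one simulates a study condition with the calibrated
generator defaults, runs the corresponding analysis, and returns tables.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd
from numpy.random import SeedSequence
from scipy.stats import spearmanr

from . import dualpulse, normalize, simcell, varstats
from .params import (
    GrowthParams,
    MeasurementParams,
    PulseScheme,
    RateProcessParams,
    StrainSpec,
)

logger = logging.getLogger(__name__)


def _defaults(rate, growth, meas):
    if rate is None or meas is None:
        cal_rate, cal_meas = simcell.default_calibration()
        rate = rate or cal_rate
        meas = meas or cal_meas
    return rate, growth or GrowthParams(), meas


def wildtype_variability(
    n_cells: int = 20000,
    pulse_min: float = 5.0,
    seed: int = 0,
    rate: Optional[RateProcessParams] = None,
    growth: Optional[GrowthParams] = None,
    meas: Optional[MeasurementParams] = None,
    min_n: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pulse wild-type experiment with background correction.

    Simulates ``n_cells`` plus a background sample, excludes binucleates,
    scales and bin-subtracts the background, and profiles per-1-µm-bin
    variability. Returns (cell table, per-bin profile).
    """
    rate, growth, meas = _defaults(rate, growth, meas)
    cells = simcell.simulate_cells(
        rate,
        growth,
        meas,
        [PulseScheme("HPG", 0.0, pulse_min)],
        n_cells,
        seed=seed,
        n_background=max(500, n_cells // 10),
    )
    cells = cells[(cells["n_nuclei"] == 1) | cells["is_background"]]
    cells = normalize.background_scale(cells, "HPG")
    cells = normalize.background_subtract_binned(cells, "HPG")
    sample = cells[~cells["is_background"]]
    profile = varstats.bin_variability_profile(sample, "HPG", min_n=min_n)
    return cells, profile


def dual_pulse_samples(
    intervals: Sequence[float],
    n_cells_per_interval: int = 10000,
    pulse_min: float = 10.0,
    seed: int = 0,
    rate: Optional[RateProcessParams] = None,
    growth: Optional[GrowthParams] = None,
    meas: Optional[MeasurementParams] = None,
) -> dict[float, pd.DataFrame]:
    """Simulate and normalize one dual-pulse sample per interval.

    The first label pulses over [0, P]; the second over [Δ, Δ+P] for each
    interval Δ. Both channels are normalized per-length and to the
    population median, ready for :func:`pulsevar.dualpulse.r2_decay_curve`.
    """
    rate, growth, meas = _defaults(rate, growth, meas)
    out: dict[float, pd.DataFrame] = {}
    for i, interval in enumerate(intervals):
        pulses = [
            PulseScheme("HPG", 0.0, pulse_min),
            PulseScheme("AHA", float(interval), pulse_min),
        ]
        cells = simcell.simulate_cells(
            rate,
            growth,
            meas,
            pulses,
            n_cells_per_interval,
            seed=SeedSequence(seed, spawn_key=(i,)),
            sample_id=f"interval_{interval:g}",
        )
        cells = cells[cells["n_nuclei"] == 1]
        cells = normalize.per_length_median_normalize(cells, "HPG")
        cells = normalize.per_length_median_normalize(cells, "AHA")
        cells["interval_min"] = float(interval)
        out[float(interval)] = cells
    return out


def decorrelation_analysis(
    intervals: Sequence[float],
    n_cells_per_interval: int = 10000,
    pulse_min: float = 10.0,
    seed: int = 0,
    n_groups: int = 10,
    **kwargs,
) -> dict:
    """Dual-pulse R² curve, decay fit, and ranked-group trajectories."""
    samples = dual_pulse_samples(
        intervals, n_cells_per_interval, pulse_min, seed, **kwargs
    )
    curve = dualpulse.r2_decay_curve(samples)
    fit = dualpulse.fit_decorrelation(curve)
    traj, pop, convergence = dualpulse.group_trajectories(samples, n_groups=n_groups)
    return {
        "samples": samples,
        "curve": curve,
        "fit": fit,
        "trajectories": traj,
        "population": pop,
        "convergence": convergence,
    }


def incubation_qcd_sweep(
    durations: Sequence[int] = tuple(range(10, 181, 10)),
    n_cells: int = 3000,
    n_seeds: int = 20,
    seed: int = 0,
    rate: Optional[RateProcessParams] = None,
) -> pd.DataFrame:
    """QCD of time-averaged incorporation versus incubation duration.

    For each seed, one cohort of cells integrates its rate over every
    duration; the QCD of the integral is recorded per duration. Averaging
    over the rate's autocorrelation time shrinks the dispersion, so the
    mean QCD must fall as duration grows. Returns a tidy frame
    (seed, duration_min, qcd) plus a ``spearman`` attribute: the rank
    correlation between duration and the seed-averaged QCD.
    """
    if rate is None:
        rate, _ = simcell.default_calibration()
    rows = []
    for k in range(n_seeds):
        tbl = simcell.simulate_time_averaged_rates(
            rate, durations, n_cells, seed=SeedSequence(seed, spawn_key=(k,))
        )
        for d in durations:
            rows.append(
                {"seed": k, "duration_min": d, "qcd": varstats.qcd(tbl[f"T{d}"].to_numpy())}
            )
    out = pd.DataFrame(rows)
    mean_curve = out.groupby("duration_min")["qcd"].mean()
    rho = spearmanr(mean_curve.index.to_numpy(), mean_curve.to_numpy()).statistic
    out.attrs["spearman"] = float(rho)
    return out


def planted_screen(
    seed: int = 0,
    n_wt_replicates: int = 5,
    planted: Sequence[tuple[str, float]] = (("high_mut", 1.5), ("low_mut", 0.6)),
    n_mutant_replicates: int = 3,
    n_cells_per_sample: int = 1000,
    rate: Optional[RateProcessParams] = None,
    growth: Optional[GrowthParams] = None,
    meas: Optional[MeasurementParams] = None,
    k: float = 1.5,
    mode: str = "mean_signal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and screen a planted-effect strain panel.

    Wild type runs ``n_wt_replicates`` replicates at s_multiplier 1;
    each planted strain gets ``n_mutant_replicates`` replicates at its
    multiplier. Returns (cell table, screen flags table).
    """
    rate, growth, meas = _defaults(rate, growth, meas)
    strains = [StrainSpec("WT", 1.0, n_wt_replicates)] + [
        StrainSpec(name, mult, n_mutant_replicates) for name, mult in planted
    ]
    cells = simcell.simulate_screen_dataset(
        strains, rate, growth, meas, n_cells_per_sample=n_cells_per_sample, seed=seed
    )
    from . import screen as screen_mod

    flags, _ = screen_mod.run_screen(cells, wildtype="WT", k=k, mode=mode,
                                     min_cells=min(100, n_cells_per_sample))
    return cells, flags
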