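"""Parameter containers for the simulator and the analysis pipeline.

All containers are plain dataclasses with eager validation: invalid values
raise :class:`ParameterError` at construction time, so downstream numerics
never see a nonsensical parameter set.

Units
-----
Lengths are micrometres (µm), times are minutes, fluorescence is in arbitrary
fluorescence-equivalent units (f.u.).  ``px_per_um`` converts pixel lengths to
micrometres (default 15.3609 px per µm, a standard calibrated microscope
scale for this assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace  # noqa: F401  (replace re-exported)
from typing import Optional

CHANNELS = ("HPG", "AHA")


class ParameterError(ValueError):
    """An invalid parameter value or combination."""


class CalibrationError(ValueError):
    """Generator calibration could not be solved from the given anchors."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class RateProcessParams:
    """Stationary log-rate process of a single cell.

    The per-cell instantaneous synthesis rate is ``mean_rate * exp(X(t) - s²/2)``
    per µm of cell length, where ``X`` is a stationary zero-mean Gaussian
    process with standard deviation ``s`` and stretched-exponential
    autocorrelation ``rho(dt) = exp(-(dt/tau_min)**beta)``.

    ``beta`` must lie in (0, 2]: in that range the kernel is positive
    definite (it is the characteristic function of a symmetric stable law),
    and ``beta = 1`` recovers the Ornstein–Uhlenbeck (Markov) special case.
    """

    mean_rate: float = 1000.0  # f.u. per µm per min
    s: float = 0.29            # stationary SD of log-rate
    tau_min: float = 50.9      # autocorrelation timescale, min
    beta: float = 1.27         # stretch exponent

    def __post_init__(self) -> None:
        _require(self.mean_rate > 0, "mean_rate must be positive")
        _require(self.s > 0, "s must be positive")
        _require(self.tau_min > 0, "tau_min must be positive")
        _require(0 < self.beta <= 2, "beta must lie in (0, 2]")


@dataclass(frozen=True)
class GrowthParams:
    """Linear growth over one cell cycle of a rod-shaped cell.

    Defaults are conventional for exponentially growing fission yeast:
    birth at 7.5 µm, division at 15 µm, a 250-min generation, and a
    half-width (``radius_um``) of 1.75 µm.  The last ``binucleate_fraction``
    of the cycle is flagged binucleate (two nuclei before septation), which
    exists so the mononucleate gate has work to do.
    """

    birth_length_um: float = 7.5
    division_length_um: float = 15.0
    generation_min: float = 250.0
    binucleate_fraction: float = 0.12
    radius_um: float = 1.75

    def __post_init__(self) -> None:
        _require(self.birth_length_um > 0, "birth_length_um must be positive")
        _require(
            self.division_length_um > self.birth_length_um,
            "division_length_um must exceed birth_length_um",
        )
        _require(self.generation_min > 0, "generation_min must be positive")
        _require(
            0 <= self.binucleate_fraction < 1,
            "binucleate_fraction must lie in [0, 1)",
        )
        _require(self.radius_um > 0, "radius_um must be positive")


@dataclass(frozen=True)
class MeasurementParams:
    """Measurement model: multiplicative channel noise plus background.

    Observed signal = true incorporation × exp(ε − sigma_meas²/2) + B, with
    ε ~ N(0, sigma_meas²) independent per channel and B lognormal with the
    given median and log-SD.  Background emulates autofluorescence plus
    nonspecific staining, measured on cells fixed immediately after analogue
    addition.
    """

    sigma_meas: float = 0.085
    background_median: float = 1000.0  # f.u.; ~20% of a typical 5-min signal
    background_log_sd: float = 0.35
    px_per_um: float = 15.3609

    def __post_init__(self) -> None:
        _require(self.sigma_meas >= 0, "sigma_meas must be nonnegative")
        _require(self.background_median > 0, "background_median must be positive")
        _require(self.background_log_sd >= 0, "background_log_sd must be nonnegative")
        _require(self.px_per_um > 0, "px_per_um must be positive")


@dataclass(frozen=True)
class PulseScheme:
    """One labelling pulse: which channel, when it starts, how long it lasts."""

    channel: str
    start_min: float = 0.0
    duration_min: float = 10.0

    def __post_init__(self) -> None:
        _require(self.channel in CHANNELS, f"channel must be one of {CHANNELS}")
        _require(self.start_min >= 0, "start_min must be nonnegative")
        _require(self.duration_min > 0, "duration_min must be positive")

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class StrainSpec:
    """A strain in the variability screen.

    ``s_multiplier`` scales the wild-type log-rate SD: >1 plants a
    high-variability mutant, <1 a low-variability one.
    """

    strain_id: str
    s_multiplier: float = 1.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        _require(self.s_multiplier > 0, "s_multiplier must be positive")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")


@dataclass(frozen=True)
class GateConfig:
    """Post-acquisition gates applied to a cell table.

    ``thickness_*`` and ``width_max_px`` are generic numeric gates on the
    columns ``thickness_px`` / ``width_px`` when those columns exist (they
    mirror imaging-flow-cytometer mask features and carry no default
    thresholds); ``extra_gates`` maps any column name to a ``(lo, hi)``
    interval.  ``require_mononucleate`` keeps only ``n_nuclei == 1`` rows.
    """

    thickness_min_px: Optional[float] = None
    thickness_max_px: Optional[float] = None
    width_max_px: Optional[float] = None
    require_mononucleate: bool = False
    extra_gates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness_min_px is not None and self.thickness_max_px is not None:
            _require(
                self.thickness_min_px < self.thickness_max_px,
                "thickness_min_px must be below thickness_max_px",
            )


@dataclass(frozen=True)
class LengthBinning:
    """Half-open length bins [k·w, (k+1)·w) with edges at integer multiples
    of the width; bins are labelled by their centre (µm)."""

    width_um: float = 1.0

    def __post_init__(self) -> None:
        _require(self.width_um > 0, "width_um must be positive")


@dataclass(frozen=True)
class VariabilitySummary:
    """Quartiles and dispersion statistics of one set of values."""

    n: int
    q1: float
    q2: float
    q3: float
    qcd: float
    cv: float
    mean: float
    sd: float


@dataclass(frozen=True)
class DecorrelationFit:
    """Fitted dual-pulse decay R²(Δt) = r2_0 · exp(−2 (Δt/τ)^β)."""

    r2_0: float
    tau_hat_min: float
    beta_hat: float
    half_decay_min: float
    residual_sse: float


def _asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
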