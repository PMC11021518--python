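"""Run configuration: a strict, nested key/value file driving the pipeline.

The YAML layout mirrors the parameter dataclasses::

    seed: 1
    experiment: population | dualpulse | screen | incubation
    rate: {mean_rate: 1000, s: 0.29, tau_min: 50.9, beta: 1.27}
    growth: {birth_length_um: 7.5, ...}
    measurement: {sigma_meas: 0.085, ...}
    population: {n_cells: 20000, pulse_min: 5.0}
    dualpulse: {intervals: [0, 20, 50], n_cells_per_interval: 10000, pulse_min: 10.0}
    screen: {strains: [{strain_id: WT, s_multiplier: 1.0, n_replicates: 5}, ...],
             n_cells_per_sample: 1000, k: 1.5, mode: mean_signal}
    incubation: {durations: [10, ..., 180], n_cells: 3000, n_seeds: 20}
    output_dir: results

Unknown keys anywhere are rejected before any computation; omitted blocks
fall back to the calibrated defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .params import (
    GrowthParams,
    MeasurementParams,
    ParameterError,
    RateProcessParams,
    StrainSpec,
)

EXPERIMENTS = ("population", "dualpulse", "screen", "incubation")

_TOP_KEYS = {
    "seed",
    "experiment",
    "rate",
    "growth",
    "measurement",
    "population",
    "dualpulse",
    "screen",
    "incubation",
    "output_dir",
}
_BLOCK_KEYS = {
    "population": {"n_cells", "pulse_min", "min_n"},
    "dualpulse": {"intervals", "n_cells_per_interval", "pulse_min", "n_groups"},
    "screen": {"strains", "n_cells_per_sample", "k", "mode", "wildtype"},
    "incubation": {"durations", "n_cells", "n_seeds"},
}


def _build(cls, block: Optional[dict], name: str):
    if block is None:
        return None
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")
    return cls(**block)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for ``pulsevar run``."""

    seed: int = 0
    experiment: str = "population"
    rate: Optional[RateProcessParams] = None
    growth: Optional[GrowthParams] = None
    measurement: Optional[MeasurementParams] = None
    options: dict = field(default_factory=dict)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ParameterError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ParameterError(f"unknown top-level key(s): {sorted(unknown)}")
        experiment = raw.get("experiment", "population")
        options = dict(raw.get(experiment, {}) or {})
        if experiment in _BLOCK_KEYS:
            bad = set(options) - _BLOCK_KEYS[experiment]
            if bad:
                raise ParameterError(
                    f"unknown key(s) in {experiment!r} block: {sorted(bad)}"
                )
        if experiment == "screen" and "strains" in options:
            options["strains"] = [
                _build(StrainSpec, s, "strains") for s in options["strains"]
            ]
        return cls(
            seed=int(raw.get("seed", 0)),
            experiment=experiment,
            rate=_build(RateProcessParams, raw.get("rate"), "rate"),
            growth=_build(GrowthParams, raw.get("growth"), "growth"),
            measurement=_build(MeasurementParams, raw.get("measurement"), "measurement"),
            options=options,
            output_dir=str(raw.get("output_dir", "results")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParameterError("config file must hold a mapping")
        return cls.from_dict(raw)
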