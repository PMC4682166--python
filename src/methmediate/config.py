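"""Configuration objects for the synthetic cohort generator and the pipeline.

``SimulationConfig`` fully determines the generative law of the synthetic
nested case-control methylation study: given a configuration, the probe
architecture, calibration constants and population truth are fixed, and the
per-cohort ``seed`` only moves the sampling noise. Configurations are frozen
and hashable so population-truth computations can be cached.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """A configuration value is out of range or inconsistent."""


#: Default leukocyte subtypes, mirroring a six-type purified-donor panel.
DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")


@dataclass(frozen=True)
class OutcomeCoeffs:
    """True coefficients of the generative logistic disease model.

    Mediator terms are expressed per 1 population s.d. of the mediator beta
    value (the generator calibrates the standardization constants internally),
    the age term per 1 s.d. of age. ``exposure_mediator_interaction`` and
    ``exposure_age_interaction`` default to zero: partial mediation through a
    purely additive pathway.
    """

    intercept: float = -3.8
    direct_smoking_log_or: float = 1.1
    mediator_log_or_per_sd: tuple[float, ...] = (-0.25, -0.15)
    age_log_or_per_sd: float = 0.3
    exposure_mediator_interaction: tuple[float, ...] = (0.0, 0.0)
    exposure_age_interaction: float = 0.0


@dataclass(frozen=True)
class BatchConfig:
    """Technical-layer settings: chip/position shifts on the logit scale."""

    samples_per_chip: int = 12
    chip_sd: float = 0.08
    position_sd: float = 0.04


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings of the synthetic methylation cohort.

    Defaults describe a prospective female cohort with roughly 5% cumulative
    lung-cancer incidence, 60% ever-smokers, a 19% relative hypomethylation of
    smoking-responsive probes in current smokers, and exponential reversal of
    the smoking shift with time since quitting (half-life in years).
    """

    n_population: int = 25_000
    n_pairs: int = 1_000
    n_probes: int = 200
    n_responsive_probes: int = 20
    n_mediators: int = 2
    n_discriminating_probes: int = 60
    smoking_prevalence: tuple[float, float, float] = (0.40, 0.30, 0.30)  # never/former/current
    relative_hypomethylation: float = 0.19
    reversal_halflife: float = 4.0
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_concentration: tuple[float, ...] = (4.0, 2.5, 1.5, 2.0, 2.0, 12.0)
    outcome_coeffs: OutcomeCoeffs = field(default_factory=OutcomeCoeffs)
    batch: BatchConfig = field(default_factory=BatchConfig)
    detection_missing_rate: float = 0.005
    noise_sd: float = 0.025
    age_range: tuple[float, float] = (45.0, 64.0)
    max_years_since_quit: float = 30.0
    followup_years: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.smoking_prevalence, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "smoking_prevalence must be three probabilities in [0,1] summing to 1"
            )
        if not (0.0 <= self.relative_hypomethylation < 1.0):
            raise ConfigurationError("relative_hypomethylation must lie in [0, 1)")
        if self.n_responsive_probes > self.n_probes:
            raise ConfigurationError("n_responsive_probes cannot exceed n_probes")
        if self.n_mediators > self.n_responsive_probes and self.n_mediators > 0:
            raise ConfigurationError("n_mediators cannot exceed n_responsive_probes")
        if self.n_discriminating_probes > self.n_probes - self.n_responsive_probes:
            raise ConfigurationError(
                "n_discriminating_probes must fit among non-responsive probes"
            )
        if len(self.cell_types) < 2:
            raise ConfigurationError("at least two cell types are required")
        if len(self.dirichlet_concentration) != len(self.cell_types):
            raise ConfigurationError("dirichlet_concentration must match cell_types length")
        if np.any(np.asarray(self.dirichlet_concentration) <= 0):
            raise ConfigurationError("dirichlet_concentration entries must be positive")
        if not (0.0 <= self.detection_missing_rate <= 1.0):
            raise ConfigurationError("detection_missing_rate must lie in [0,1]")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ConfigurationError("noise_sd must be finite and nonnegative")
        if self.reversal_halflife <= 0:
            raise ConfigurationError("reversal_halflife must be positive")
        oc = self.outcome_coeffs
        if len(oc.mediator_log_or_per_sd) != self.n_mediators:
            raise ConfigurationError(
                "outcome_coeffs.mediator_log_or_per_sd must have one entry per mediator"
            )
        if len(oc.exposure_mediator_interaction) != self.n_mediators:
            raise ConfigurationError(
                "outcome_coeffs.exposure_mediator_interaction must have one entry per mediator"
            )
        for name in ("intercept", "direct_smoking_log_or", "age_log_or_per_sd"):
            if not np.isfinite(getattr(oc, name)):
                raise ConfigurationError(f"outcome_coeffs.{name} must be finite")

    def with_(self, **kwargs: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


#: Discovery-cohort-scale preset: 132 case-control pairs from a ~20k population.
def discovery_scale_config(**overrides: Any) -> SimulationConfig:
    base = SimulationConfig(n_population=8_000, n_pairs=132)
    return base.with_(**overrides) if overrides else base


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage parameters (prevalence weighting, Monte Carlo sizes)."""

    prevalence: float = 0.01
    n_mc: int = 400
    n_bootstrap: int = 200
    probe_missing_threshold: float = 0.20
    sample_missing_threshold: float = 0.05
    fwer_cells: float = 0.01
    fwer_scan: float = 0.05
    min_stratum_n: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie strictly in (0,1)")
        if self.n_mc < 1:
            raise ConfigurationError("n_mc must be >= 1")
        if self.n_bootstrap < 2:
            raise ConfigurationError("n_bootstrap must be >= 2")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run: stage selection plus all parameters."""

    stages: tuple[str, ...] = (
        "simulate",
        "preprocess",
        "deconvolve",
        "scan",
        "mediate",
        "report",
    )
    out_dir: str = "methmediate_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"

    VALID_STAGES = ("simulate", "preprocess", "deconvolve", "scan", "mediate", "report")

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in self.VALID_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown pipeline stages: {unknown}")


# ---------------------------------------------------------------------------
# (De)serialization with strict key checking
# ---------------------------------------------------------------------------

def _build(cls, data: Mapping[str, Any], path: str):
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"{path}: unknown configuration keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        ftype = fields[name].type
        if name in ("outcome_coeffs",):
            value = _build(OutcomeCoeffs, value, f"{path}.{name}")
        elif name in ("batch",):
            value = _build(BatchConfig, value, f"{path}.{name}")
        elif name in ("simulation",):
            value = _build(SimulationConfig, value, f"{path}.{name}")
        elif name in ("analysis",):
            value = _build(AnalysisConfig, value, f"{path}.{name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def _as_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def config_to_dict(config: Any) -> dict:
    return _as_plain(config)


def run_config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    return _build(RunConfig, data, "run_config")


def simulation_config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    return _build(SimulationConfig, data, "simulation_config")


def load_run_config(path: str) -> RunConfig:
    """Load a pipeline configuration from YAML/JSON, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return run_config_from_dict(data)


def save_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
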