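"""Pipeline configuration with validated defaults.

Defaults encode the published operating point of the method: GA crossover 0.6,
mutation 0.033, population 20 x 20 generations; geometric-PSO recombination
weights 0.33/0.34/0.33 with a logistic-regression wrapper; linear SVM with
C = 0.1 evaluated by 10-fold cross-validation; LSTM stacks 75-50-25-15
(weekly-quality metric) and 100-80-60-40 (consistency metric), tanh, dropout
0.2, on 24x1 hourly windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ConfigError


@dataclass
class GeneticConfig:
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    population: int = 20
    generations: int = 20
    report_frequency: int = 20
    seed: int = 1
    tournament_size: int = 2
    elitism: int = 1

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"genetic.{name} must lie in [0, 1], got {v}")
        for name in ("population", "generations", "tournament_size"):
            if getattr(self, name) < (0 if name == "generations" else 1):
                raise ConfigError(f"genetic.{name} out of range")


@dataclass
class PsoConfig:
    inertia_weight: float = 0.33
    individual_weight: float = 0.34
    social_weight: float = 0.33
    population: int = 20
    iterations: int = 20
    fitness_classifier: str = "logistic"  # "logistic" | "svm"
    mutation_prob: float | None = None  # None -> 1 / n_features
    seed: int = 1

    def validate(self) -> None:
        total = self.inertia_weight + self.individual_weight + self.social_weight
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"pso weights must sum to 1 (inertia+individual+social = {total})"
            )
        if min(self.inertia_weight, self.individual_weight, self.social_weight) < 0:
            raise ConfigError("pso weights must be non-negative")
        if self.population < 1 or self.iterations < 0:
            raise ConfigError("pso.population/iterations out of range")
        if self.fitness_classifier not in ("logistic", "svm"):
            raise ConfigError("pso.fitness_classifier must be 'logistic' or 'svm'")
        if self.mutation_prob is not None and not (0.0 <= self.mutation_prob <= 1.0):
            raise ConfigError("pso.mutation_prob must lie in [0, 1]")


@dataclass
class ExtractorSpec:
    """Architecture and training schedule of the LSTM feature extractor."""

    layer_sizes: tuple[int, ...] = (75, 50, 25, 15)
    activation: str = "tanh"
    dropout: float = 0.2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    patience: int = 25
    seed: int = 0

    def validate(self) -> None:
        if not self.layer_sizes or any(s < 1 for s in self.layer_sizes):
            raise ConfigError("extractor.layer_sizes must be positive integers")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("extractor.dropout must lie in [0, 1)")
        if self.activation != "tanh":
            raise ConfigError("extractor.activation: only 'tanh' is supported")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("extractor training schedule out of range")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ConfigError("extractor.val_fraction must lie in [0, 1)")

    @property
    def feature_dim(self) -> int:
        return self.layer_sizes[-1]


@dataclass
class ScoringConfig:
    """Sleep/wake scoring and metric-construction settings."""

    cole_threshold: float = 1.0
    webster_rescoring: bool = False
    persistent_sleep_run: int = 5
    search_window: tuple[float, float] = (18.0, 12.0)  # rest-interval search, clock h
    # 0-3 subscore band upper edges (inclusive for "better" side), PSQI-style
    efficiency_bands: tuple[float, float, float] = (85.0, 75.0, 65.0)  # >=85 -> 0 ...
    latency_bands: tuple[float, float, float] = (15.0, 30.0, 60.0)  # <=15 -> 0 ...
    waso_bands: tuple[float, float, float] = (20.0, 40.0, 60.0)
    duration_bands: tuple[float, float, float] = (420.0, 360.0, 300.0)  # >=420 -> 0 ...
    cons_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    cons_dispersion: str = "sd"  # "sd" | "variance"
    weekend_diff_mode: str = "midpoint"  # "midpoint" | "duration"

    def validate(self) -> None:
        if abs(sum(self.cons_weights) - 1.0) > 1e-9:
            raise ConfigError("scoring.cons_weights must sum to 1")
        if self.cons_dispersion not in ("sd", "variance"):
            raise ConfigError("scoring.cons_dispersion must be 'sd' or 'variance'")
        if self.weekend_diff_mode not in ("midpoint", "duration"):
            raise ConfigError("scoring.weekend_diff_mode must be 'midpoint' or 'duration'")
        if self.persistent_sleep_run < 1:
            raise ConfigError("scoring.persistent_sleep_run must be >= 1")


@dataclass
class PipelineConfig:
    metric: str = "SleepQualWeek"  # "SleepQualWeek" | "SleepCons"
    window_len: int = 24
    step: int = 12
    norm_scope: str = "per_record"  # "per_record" | "per_window"
    hour_alignment: str = "record"  # "record" | "clock"
    stat_features_on_normalized: bool = True
    svm_c: float = 0.1
    cv_folds: int = 10
    wrapper_cv_folds: int = 5
    seed: int = 1
    genetic: GeneticConfig = field(default_factory=GeneticConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    extractor_sqw: ExtractorSpec = field(
        default_factory=lambda: ExtractorSpec(layer_sizes=(75, 50, 25, 15))
    )
    extractor_cons: ExtractorSpec = field(
        default_factory=lambda: ExtractorSpec(layer_sizes=(100, 80, 60, 40))
    )
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def validate(self) -> None:
        if self.metric not in ("SleepQualWeek", "SleepCons"):
            raise ConfigError("metric must be 'SleepQualWeek' or 'SleepCons'")
        if self.svm_c <= 0:
            raise ConfigError("svm_c must be > 0")
        if self.cv_folds < 2 or self.wrapper_cv_folds < 2:
            raise ConfigError("cv folds must be >= 2")
        if self.norm_scope not in ("per_record", "per_window"):
            raise ConfigError("norm_scope must be 'per_record' or 'per_window'")
        if self.hour_alignment not in ("record", "clock"):
            raise ConfigError("hour_alignment must be 'record' or 'clock'")
        if self.window_len < 1 or self.step < 1:
            raise ConfigError("window_len and step must be >= 1")
        self.genetic.validate()
        self.pso.validate()
        self.extractor_sqw.validate()
        self.extractor_cons.validate()
        self.scoring.validate()

    @property
    def extractor(self) -> ExtractorSpec:
        return self.extractor_sqw if self.metric == "SleepQualWeek" else self.extractor_cons


_NESTED = {
    "genetic": GeneticConfig,
    "pso": PsoConfig,
    "extractor_sqw": ExtractorSpec,
    "extractor_cons": ExtractorSpec,
    "scoring": ScoringConfig,
}


def _apply(obj, data: dict, prefix: str = ""):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown config key '{prefix}{key}'")
        if key in _NESTED and prefix == "":
            if not isinstance(value, dict):
                raise ConfigError(f"config key '{key}' must be a mapping")
            _apply(getattr(obj, key), value, prefix=f"{key}.")
        else:
            current = getattr(obj, key)
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            setattr(obj, key, value)
    return obj


def config_from_dict(data: dict | None) -> PipelineConfig:
    cfg = PipelineConfig()
    if data:
        _apply(cfg, data)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unspecified keys keep the published defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return config_from_dict(data)
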