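"""Run configuration: every tunable of the pipeline in one dataclass.

Defaults encode the method's standard analysis constants (0.1-70 Hz
order-8 Butterworth, 150-s epoch, 2-s/1-s segments, 0.5 Hz bins capped
at 45 Hz, 2 principal components per pair); the GA/SVM hyperparameters
are this package's own choices, exposed here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm feature-subset search settings."""

    population: int = 50
    generations: int = 100
    crossover_p: float = 0.5  # per-bit parent choice in uniform crossover
    mutation_p: float = 0.01  # per-bit flip probability
    elitism: int = 2
    tournament: int = 3
    cv_folds: int = 5
    parsimony: float = 0.01  # penalty weight on mask size / n_features


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings for extraction, training and classification."""

    filter_low_hz: float = 0.1
    filter_high_hz: float = 70.0
    filter_order: int = 8
    filter_zero_phase: bool = True
    epoch_duration_s: float = 150.0
    epoch_start_s: float = 0.0
    segment_length_s: float = 2.0
    segment_step_s: float = 1.0
    estimator: str = "median"  # robust across-segment estimator
    selection: str = "auc"  # component selection rule
    svm_c: float = 1.0
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int = 0
    min_per_class: int = 4  # below this a gender stratum falls back to pooled
    ci_level: float = 0.95

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    ga_data = data.pop("ga", {})
    ga = GAConfig(**ga_data) if isinstance(ga_data, dict) else ga_data
    return PipelineConfig(ga=ga, **data)
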