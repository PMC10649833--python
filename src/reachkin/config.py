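"""Pipeline configuration: one YAML/JSON-serializable block of settings.

The block nests the task constants, the cohort sampling plan, the metric
options, and the statistics options; every field defaults to the protocol
/ generator defaults, and a config round-trips through its file form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .kinematic_metrics import MetricOptions
from .synthetic_cohort import CohortSpec
from .task_protocol import TaskConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    metrics: MetricOptions = field(default_factory=MetricOptions)
    alpha: float = 0.05
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cohort = dataclasses.replace(self.cohort, seed=seed)
        return dataclasses.replace(self, seed=seed, cohort=cohort)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "task": dataclasses.asdict(self.task),
            "cohort": dataclasses.asdict(self.cohort),
            "metrics": dataclasses.asdict(self.metrics),
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        return cls(
            task=TaskConfig(**data.get("task", {})),
            cohort=CohortSpec(**data.get("cohort", {})),
            metrics=MetricOptions(**data.get("metrics", {})),
            alpha=float(data.get("alpha", 0.05)),
            seed=int(data.get("seed", 0)),
        )


def load_config(path: Optional[Path]) -> PipelineConfig:
    """Load a YAML (or JSON) config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path: Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=1))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
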