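"""Run configuration, YAML round-tripping and seed management."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .tasks import TaskConfig

__all__ = ["RunConfig", "load_config", "save_config", "derive_seed"]

_STAGES = {"init": 0, "taskgen": 1, "train": 2, "analyze": 3,
           "inactivate": 4, "size_sweep": 5, "fixture": 6, "eval": 7}


@dataclass
class RunConfig:
    """Everything needed to regenerate one pipeline run."""

    family: str = "hf"
    n_rec: int | None = None  # None -> family's scaled default
    task: dict = field(default_factory=dict)  # TaskConfig overrides
    trainer: dict = field(default_factory=dict)  # trainer-spec overrides
    analysis_policy: str | None = None  # None -> family default
    inactivation_grid: list | None = None
    n_eval_trials: int = 200
    root_seed: int = 0
    output_dir: str = "run_output"

    def task_config(self) -> TaskConfig:
        from .presets import scaled_task_config
        base = scaled_task_config("pyrl" if self.family.startswith("pyrl")
                                  else self.family,
                                  seed=derive_seed(self.root_seed, "taskgen"))
        overrides = dict(self.task)
        for key in ("coherence_levels_motion", "coherence_levels_color"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return TaskConfig(**{**_task_dict(base), **overrides})


def _task_dict(cfg: TaskConfig) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(TaskConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.task_config()  # validate task overrides eagerly
    if cfg.family not in ("hf", "pycog", "pyrl", "rhebb"):
        raise ValueError(f"unknown family {cfg.family!r}")
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def derive_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the root seed.

    Counter-based: each (stage, index) pair gets an independent stream via
    numpy's SeedSequence spawning; results stay below 2**31.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=root_seed,
                                spawn_key=(_STAGES[stage], index))
    return int(ss.generate_state(1)[0] % (2 ** 31))
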