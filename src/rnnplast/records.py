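"""Training records and HDF5 persistence of parameters, records and trials."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .networks import Architecture, GateParameters, NetworkParameters
from .tasks import TaskConfig, Trial, TrialBatch

__all__ = [
    "TrainingRecord",
    "save_parameters",
    "load_parameters",
    "save_record",
    "load_record",
    "save_trials",
    "load_trials",
]


@dataclass
class TrainingRecord:
    """Snapshot of one training run: initial and final parameters plus trace."""

    family: str
    W_init: NetworkParameters
    W_last: NetworkParameters
    performance_trace: np.ndarray  # (checkpoints, 2): iteration, accuracy
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def final_accuracy(self) -> float:
        if len(self.performance_trace) == 0:
            return float("nan")
        return float(self.performance_trace[-1, 1])


def _write_params(grp: h5py.Group, p: NetworkParameters) -> None:
    grp.create_dataset("W_rec", data=p.W_rec)
    grp.create_dataset("W_in", data=p.W_in)
    grp.create_dataset("b_x", data=p.b_x)
    if p.W_out is not None:
        grp.create_dataset("W_out", data=p.W_out)
        grp.create_dataset("b_out", data=p.b_out)
    if p.gates is not None:
        g = grp.create_group("gates")
        for name in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r"):
            g.create_dataset(name, data=getattr(p.gates, name))


def _read_params(grp: h5py.Group) -> NetworkParameters:
    gates = None
    if "gates" in grp:
        g = grp["gates"]
        gates = GateParameters(**{n: g[n][()] for n in
                                  ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r")})
    return NetworkParameters(
        W_rec=grp["W_rec"][()],
        W_in=grp["W_in"][()],
        b_x=grp["b_x"][()],
        W_out=grp["W_out"][()] if "W_out" in grp else None,
        b_out=grp["b_out"][()] if "b_out" in grp else None,
        gates=gates,
    )


def _arch_attrs(arch: Architecture) -> str:
    d = {
        "family": arch.family, "n_in": arch.n_in, "n_rec": arch.n_rec,
        "n_out": arch.n_out, "activation": arch.activation, "tau": arch.tau,
        "dt": arch.dt, "noise_std_rec": arch.noise_std_rec,
        "output_unit_index": arch.output_unit_index,
        "constant_input_units": list(arch.constant_input_units),
        "has_dale": arch.dale_signs is not None,
        "has_mask": arch.plasticity_mask is not None,
    }
    return json.dumps(d)


def save_parameters(path, params: NetworkParameters,
                    arch: Architecture | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_params(f, params)
        if arch is not None:
            f.attrs["architecture"] = _arch_attrs(arch)
            if arch.dale_signs is not None:
                f.create_dataset("dale_signs", data=arch.dale_signs)
            if arch.plasticity_mask is not None:
                f.create_dataset("plasticity_mask",
                                 data=arch.plasticity_mask.astype(np.uint8))


def load_parameters(path) -> NetworkParameters:
    with h5py.File(path, "r") as f:
        return _read_params(f)


def save_record(path, record: TrainingRecord,
                arch: Architecture | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["family"] = record.family
        f.attrs["seed"] = record.seed
        f.attrs["config"] = json.dumps(record.config, default=str)
        if arch is not None:
            f.attrs["architecture"] = _arch_attrs(arch)
            if arch.dale_signs is not None:
                f.create_dataset("dale_signs", data=arch.dale_signs)
            if arch.plasticity_mask is not None:
                f.create_dataset("plasticity_mask",
                                 data=arch.plasticity_mask.astype(np.uint8))
        _write_params(f.create_group("init"), record.W_init)
        _write_params(f.create_group("last"), record.W_last)
        f.create_dataset("performance_trace", data=record.performance_trace)


def load_record(path) -> TrainingRecord:
    with h5py.File(path, "r") as f:
        return TrainingRecord(
            family=f.attrs["family"],
            W_init=_read_params(f["init"]),
            W_last=_read_params(f["last"]),
            performance_trace=f["performance_trace"][()],
            seed=int(f.attrs["seed"]),
            config=json.loads(f.attrs["config"]),
        )


_CTX_CODE = {"motion": 0, "color": 1}
_CTX_NAME = {v: k for k, v in _CTX_CODE.items()}


def save_trials(path, batch: TrialBatch) -> None:
    """Persist a trial batch: stacked arrays plus a JSON config sidecar attr."""
    cfg = batch.config
    with h5py.File(path, "w") as f:
        f.attrs["task_config"] = json.dumps({
            "coherence_levels_motion": list(cfg.coherence_levels_motion),
            "coherence_levels_color": list(cfg.coherence_levels_color),
            "noise_std_motion": cfg.noise_std_motion,
            "noise_std_color": cfg.noise_std_color,
            "dt": cfg.dt, "trial_duration": cfg.trial_duration,
            "encoding_mode": cfg.encoding_mode,
            "baseline_input": cfg.baseline_input,
            "zero_coherence_policy": cfg.zero_coherence_policy,
            "seed": cfg.seed,
        })
        f.create_dataset("inputs", data=batch.inputs_array())
        f.create_dataset("context", data=np.array(
            [_CTX_CODE[t.context] for t in batch]))
        f.create_dataset("d_m", data=np.array([t.d_m for t in batch]))
        f.create_dataset("d_c", data=np.array([t.d_c for t in batch]))
        f.create_dataset("correct_choice", data=batch.correct_choices())


def load_trials(path) -> TrialBatch:
    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["task_config"])
        raw["coherence_levels_motion"] = tuple(raw["coherence_levels_motion"])
        raw["coherence_levels_color"] = tuple(raw["coherence_levels_color"])
        cfg = TaskConfig(**raw)
        inputs = f["inputs"][()]
        ctx = f["context"][()]
        d_m = f["d_m"][()]
        d_c = f["d_c"][()]
        correct = f["correct_choice"][()]
    trials = [Trial(inputs=inputs[i], context=_CTX_NAME[int(ctx[i])],
                    d_m=float(d_m[i]), d_c=float(d_c[i]),
                    correct_choice=int(correct[i]), config=cfg)
              for i in range(len(ctx))]
    return TrialBatch(trials=trials, config=cfg)
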