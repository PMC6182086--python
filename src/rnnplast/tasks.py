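"""Context-dependent integration task: trial generation, targets and rewards.

The task is the two-alternative sensory integration task used to probe
cognitive flexibility in prefrontal cortex: on every trial the network
receives noisy motion evidence, noisy color evidence and a binary context
cue that tells it which modality is currently relevant.  The correct choice
is the sign of the context-relevant coherence; the irrelevant modality must
be ignored.

Sensory inputs are piecewise-constant offsets plus i.i.d. Gaussian noise,

    u_m(t) = d_m + rho_m(t),    u_c(t) = d_c + rho_c(t),

where d_m / d_c are the signed motion / color coherences.  Two encodings
are supported: a signed two-channel code (one channel per modality, sign
carries the feature; used by the tanh-unit model families) and a separated
four-channel code (one non-negative channel per feature; used by the
rectified-linear families).  Context is always a pair of one-hot binary
channels (u_cm, u_cc).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "Trial",
    "TrialBatch",
    "make_trial",
    "make_batch",
    "target_series",
    "CHOICE1",
    "CHOICE2",
    "STAY",
]

CHOICE1 = 1
CHOICE2 = 2
STAY = 0

MOTION = "motion"
COLOR = "color"

_FAMILIES = ("hf", "pycog", "pyrl", "rhebb")

# channel order of the separated (rectified) encoding
SEPARATED_CHANNELS = ("motion-right", "motion-left", "color-red", "color-green")


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus statistics and discretization of the integration task.

    Coherence lists must be symmetric about zero.  ``dt`` and
    ``trial_duration`` are in milliseconds; the number of simulation steps
    is ``trial_duration / dt``.
    """

    coherence_levels_motion: tuple = (-0.04, -0.02, -0.01, 0.01, 0.02, 0.04)
    coherence_levels_color: tuple = (-0.04, -0.02, -0.01, 0.01, 0.02, 0.04)
    noise_std_motion: float = 0.04
    noise_std_color: float = 0.04
    dt: float = 1.0
    trial_duration: float = 30.0
    encoding_mode: Literal["signed_2channel", "separated_4channel"] = "signed_2channel"
    baseline_input: float = 0.2  # offset of the separated non-negative channels
    zero_coherence_policy: Literal["reject", "random_target"] = "reject"
    seed: int = 0

    def __post_init__(self):
        for levels in (self.coherence_levels_motion, self.coherence_levels_color):
            if len(levels) == 0:
                raise ValueError("coherence level list must be nonempty")
            if not np.allclose(sorted(levels), sorted(-np.asarray(levels))):
                raise ValueError("coherence levels must be symmetric about zero")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.trial_duration / self.dt
        if self.trial_duration <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration must be a positive multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))

    @property
    def n_in(self) -> int:
        return 4 if self.encoding_mode == "signed_2channel" else 6


@dataclass
class Trial:
    """One realized trial: input time series plus ground truth."""

    inputs: np.ndarray  # (T, N_in)
    context: str  # "motion" | "color"
    d_m: float
    d_c: float
    correct_choice: int  # CHOICE1 | CHOICE2
    target_outputs: np.ndarray | None = None
    error_mask: np.ndarray | None = None
    reward_schedule: np.ndarray | None = None
    config: TaskConfig | None = None


@dataclass
class TrialBatch:
    trials: list
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def inputs_array(self) -> np.ndarray:
        """Stack trial inputs into a (n_trials, T, N_in) array."""
        return np.stack([t.inputs for t in self.trials])

    def correct_choices(self) -> np.ndarray:
        return np.array([t.correct_choice for t in self.trials])

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)


def _relevant_coherence(context: str, d_m: float, d_c: float) -> float:
    if context == MOTION:
        return d_m
    if context == COLOR:
        return d_c
    raise ValueError(f"unknown context {context!r}")


def make_trial(config: TaskConfig, context: str, d_m: float, d_c: float,
               rng: np.random.Generator) -> Trial:
    """Generate one trial of the context-dependent integration task.

    The context-relevant coherence determines the correct choice
    (positive -> choice 1, negative -> choice 2).  Zero relevant coherence
    is rejected unless the config maps it to a random target.
    """
    rel = _relevant_coherence(context, d_m, d_c)
    if rel == 0:
        if config.zero_coherence_policy == "reject":
            raise ValueError("zero context-relevant coherence: correct choice undefined")
        correct = CHOICE1 if rng.random() < 0.5 else CHOICE2
    else:
        correct = CHOICE1 if rel > 0 else CHOICE2

    T = config.n_steps
    u_ctx = np.zeros((T, 2))
    u_ctx[:, 0 if context == MOTION else 1] = 1.0

    if config.encoding_mode == "signed_2channel":
        sens = np.empty((T, 2))
        sens[:, 0] = d_m + rng.normal(0.0, config.noise_std_motion, T)
        sens[:, 1] = d_c + rng.normal(0.0, config.noise_std_color, T)
    else:
        b = config.baseline_input
        offs = np.array([
            b + max(d_m, 0.0),
            b + max(-d_m, 0.0),
            b + max(d_c, 0.0),
            b + max(-d_c, 0.0),
        ])
        noise = np.empty((T, 4))
        noise[:, 0:2] = rng.normal(0.0, config.noise_std_motion, (T, 2))
        noise[:, 2:4] = rng.normal(0.0, config.noise_std_color, (T, 2))
        sens = offs[None, :] + noise

    inputs = np.concatenate([sens, u_ctx], axis=1)
    return Trial(inputs=inputs, context=context, d_m=d_m, d_c=d_c,
                 correct_choice=correct, config=config)


def make_batch(config: TaskConfig, n: int,
               context_policy: Literal["alternating", "random"] = "alternating",
               rng: np.random.Generator | None = None,
               family: str | None = None) -> TrialBatch:
    """Generate ``n`` independent trials with balanced or random contexts.

    Coherences are drawn uniformly from the configured level lists.  If
    ``family`` is given, targets / masks / reward schedules for that model
    family are attached to every trial.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = []
    for i in range(n):
        if context_policy == "alternating":
            context = MOTION if i % 2 == 0 else COLOR
        elif context_policy == "random":
            context = MOTION if rng.random() < 0.5 else COLOR
        else:
            raise ValueError(f"unknown context policy {context_policy!r}")
        d_m = float(rng.choice(config.coherence_levels_motion))
        d_c = float(rng.choice(config.coherence_levels_color))
        trial = make_trial(config, context, d_m, d_c, rng)
        if family is not None:
            tgt, mask = target_series(trial, family)
            if family == "pyrl":
                trial.reward_schedule = tgt
            else:
                trial.target_outputs = tgt
            trial.error_mask = mask
        trials.append(trial)
    return TrialBatch(trials=trials, config=config)


def target_series(trial: Trial, family: str):
    """Target outputs and error mask (or reward schedule) for a model family.

    * ``hf``: scalar target, 0 at the first step and +/-1 at the last step;
      the mask selects exactly those two time points.
    * ``rhebb``: scalar +/-1 target at the last step only (used to compute
      the end-of-trial reward, not a squared-error loss).
    * ``pycog``: two-channel one-hot target; only the final step is scored.
    * ``pyrl``: per-time, per-action reward values -- at the decision step
      the correct action earns +1 and the others 0; any step on which
      fixation would be broken earns -1 (no fixation epoch by default, so
      pre-decision rows are zero).
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    T = trial.inputs.shape[0]
    mask = np.zeros(T, dtype=bool)
    sign = 1.0 if trial.correct_choice == CHOICE1 else -1.0

    if family == "hf":
        tgt = np.zeros((T, 1))
        tgt[-1, 0] = sign
        mask[0] = True
        mask[-1] = True
        return tgt, mask
    if family == "rhebb":
        tgt = np.zeros((T, 1))
        tgt[-1, 0] = sign
        mask[-1] = True
        return tgt, mask
    if family == "pycog":
        tgt = np.zeros((T, 2))
        tgt[-1, 0 if trial.correct_choice == CHOICE1 else 1] = 1.0
        mask[-1] = True
        return tgt, mask
    # pyrl: reward per (time, action) with actions (choice1, choice2, stay)
    rew = np.zeros((T, 3))
    rew[-1, 0] = 1.0 if trial.correct_choice == CHOICE1 else 0.0
    rew[-1, 1] = 1.0 if trial.correct_choice == CHOICE2 else 0.0
    mask[-1] = True
    return rew, mask


def signed_to_separated_offsets(d: float, baseline: float) -> tuple[float, float]:
    """Map a signed coherence to the (favored, anti) separated-channel offsets."""
    return baseline + max(d, 0.0), baseline + max(-d, 0.0)
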