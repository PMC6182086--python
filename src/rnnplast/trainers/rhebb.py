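"""Reward-modulated Hebbian trainer (node-perturbation rule).

Learning is driven by exploratory perturbations of the recurrent units.
Every time step, each synapse accumulates a superlinear function of the
product of its presynaptic rate and the postsynaptic potential's deviation
from a short-time running average:

    e_ij(t) = e_ij(t-1) + S( r_j(t-1) * (x_i(t) - xbar_i) ),   S(x) = x^3.

At the end of the trial the accumulated eligibility is converted into a
weight change gated by the reward-prediction error,

    dW_ij = eta * e_ij * (R - Rbar),

where R is the trial reward -- the negative absolute deviation of the
response from the optimal response -- and Rbar a running average of reward
previously received for the same stimulus condition.  The cubic
superlinearity keeps only large noise-driven fluctuations effective, which
is what concentrates plasticity on few synapses.

Exploration follows the node-perturbation scheme: sparse, strong kicks
(uniform amplitude, low per-step probability per unit) injected directly
into the membrane potentials, rather than the small continuous state noise
of the gradient-trained families.  Row index i is the postsynaptic unit,
column j the presynaptic unit.  The output unit and the constant-input
units have their incoming synapses updated like any others; they are
excluded later, at analysis time.

The trial-by-trial training loop is compiled with numba; the rule's
primitive operations (``rhebb_accumulate``, ``rhebb_apply``) are plain
numpy and define the reference semantics the kernel follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..networks import Architecture, NetworkParameters, accuracy
from ..records import TrainingRecord
from ..tasks import MOTION, COLOR, TaskConfig, make_batch, make_trial
from ..tasks import CHOICE1

__all__ = ["RHebbConfig", "EligibilityState", "rhebb_accumulate",
           "rhebb_apply", "rhebb_train"]


@dataclass
class RHebbConfig:
    eta: float = 0.25
    superlinear_exponent: int = 3
    running_avg_tau: float | None = 5.0  # ms; None -> trial duration
    reward_avg_scheme: str = "per_condition_running_mean"
    reward_avg_rate: float = 0.5  # EMA rate for Rbar
    n_trials: int = 40_000
    max_dw: float | None = 2e-4  # elementwise clip on one trial's update
    kick_probability: float = 0.003  # per unit and time step
    kick_amplitude: float = 0.5  # uniform(-amp, amp) potential kicks
    settle_steps: int = 100  # eligibility ignored before this step
    response_window: int = 50  # response = mean output over the last steps
    eta_decay_trials: float | None = 15_000.0  # eta/(1 + trial/decay)
    stop_accuracy: float = 0.85
    n_validation: int = 500
    eval_every: int = 4000

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        p = self.superlinear_exponent
        if p < 3 or p % 2 == 0:
            raise ValueError("superlinear exponent must be odd and >= 3")


@dataclass
class EligibilityState:
    e: np.ndarray  # (N, N) per-synapse trace
    x_bar: np.ndarray  # (N,) running-average potentials
    R_bar: dict = field(default_factory=dict)  # condition -> reward baseline

    @classmethod
    def zeros(cls, n_rec: int) -> "EligibilityState":
        return cls(e=np.zeros((n_rec, n_rec)), x_bar=np.zeros(n_rec))

    def reset_trial(self) -> None:
        self.e[:] = 0.0


def rhebb_accumulate(state: EligibilityState, r_prev: np.ndarray,
                     x_now: np.ndarray, config: RHebbConfig) -> EligibilityState:
    """Add S(r_j(t-1) * (x_i(t) - xbar_i)) to every trace entry.

    ``state.x_bar`` must already hold the running average for this step
    (the caller updates it before accumulating).  Nothing but ``e`` is
    mutated.
    """
    if r_prev.shape != x_now.shape or x_now.shape != state.x_bar.shape:
        raise ValueError("shape mismatch between rates, potentials and x_bar")
    dev = x_now - state.x_bar
    state.e += (dev[:, None] * r_prev[None, :]) ** config.superlinear_exponent
    return state


def rhebb_apply(params: NetworkParameters, state: EligibilityState, R: float,
                config: RHebbConfig, condition=("global",)):
    """End-of-trial update dW = eta * e * (R - Rbar); refresh Rbar.

    The first trial of a condition only initializes its reward baseline
    (no weight change).  The per-trial update is clipped elementwise at
    ``max_dw`` for stability.  Returns the applied dW matrix.
    """
    if not np.isfinite(R):
        raise FloatingPointError("non-finite reward")
    if config.reward_avg_scheme == "global_running_mean":
        condition = ("global",)
    if condition not in state.R_bar:
        state.R_bar[condition] = R
        return np.zeros_like(params.W_rec)
    r_bar = state.R_bar[condition]
    dw = config.eta * state.e * (R - r_bar)
    if config.max_dw is not None:
        np.clip(dw, -config.max_dw, config.max_dw, out=dw)
    params.W_rec += dw
    beta = config.reward_avg_rate
    state.R_bar[condition] = (1.0 - beta) * r_bar + beta * R
    return dw


# ---------------------------------------------------------------------------
# compiled training kernel

_KERNEL = None


def _get_kernel():
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    from numba import njit

    @njit(cache=True)
    def kernel(W, Win, b_x, const_drive, out_idx, levels_m, levels_c,
               n_trials, T, alpha, sigma_m, sigma_c, rho_x, kick_p, kick_amp,
               xbar_k, eta0, eta_decay, max_dw, beta, exponent, settle,
               resp_win, per_condition, Rbar, seen, tr0, seed):
        np.random.seed(seed)
        N = W.shape[0]
        nlm = len(levels_m)
        nlc = len(levels_c)
        correct = np.zeros(n_trials)
        for tr in range(n_trials):
            ctx = (tr0 + tr) % 2
            im = np.random.randint(nlm)
            ic = np.random.randint(nlc)
            dm = levels_m[im]
            dc = levels_c[ic]
            rel = dm if ctx == 0 else dc
            target = 1.0 if rel > 0 else -1.0
            x = np.zeros(N)
            r = np.zeros(N)
            xbar = np.zeros(N)
            e = np.zeros((N, N))
            zsum = 0.0
            for t in range(T):
                u0 = dm + np.random.normal(0.0, sigma_m)
                u1 = dc + np.random.normal(0.0, sigma_c)
                drive = W @ r
                for i in range(N):
                    drive[i] += (Win[i, 0] * u0 + Win[i, 1] * u1
                                 + Win[i, 2] * (1.0 - ctx) + Win[i, 3] * ctx
                                 + b_x[i] + const_drive[i])
                    if rho_x > 0.0:
                        drive[i] += np.random.normal(0.0, rho_x)
                for i in range(N):
                    kick = 0.0
                    if np.random.random() < kick_p:
                        kick = np.random.uniform(-kick_amp, kick_amp)
                    x[i] = (1.0 - alpha) * x[i] + alpha * drive[i] + kick
                    xbar[i] = (1.0 - xbar_k) * xbar[i] + xbar_k * x[i]
                if t >= settle:
                    for i in range(N):
                        dev = x[i] - xbar[i]
                        for j in range(N):
                            m = dev * r[j]
                            acc = m
                            for _ in range(exponent - 1):
                                acc *= m
                            e[i, j] += acc
                for i in range(N):
                    r[i] = np.tanh(x[i])
                if t >= T - resp_win:
                    zsum += r[out_idx]
            z = zsum / resp_win
            R = -abs(z - target)
            correct[tr] = 1.0 if z * target > 0 else 0.0
            ci = ctx if per_condition else 0
            ji = im if per_condition else 0
            ki = ic if per_condition else 0
            if seen[ci, ji, ki]:
                eta = eta0
                if eta_decay > 0:
                    eta = eta0 / (1.0 + (tr0 + tr) / eta_decay)
                fac = eta * (R - Rbar[ci, ji, ki])
                for i in range(N):
                    for j in range(N):
                        dw = fac * e[i, j]
                        if max_dw > 0:
                            if dw > max_dw:
                                dw = max_dw
                            elif dw < -max_dw:
                                dw = -max_dw
                        W[i, j] += dw
                Rbar[ci, ji, ki] = (1.0 - beta) * Rbar[ci, ji, ki] + beta * R
            else:
                Rbar[ci, ji, ki] = R
                seen[ci, ji, ki] = True
        return correct

    _KERNEL = kernel
    return _KERNEL


def rhebb_train(params: NetworkParameters, arch: Architecture,
                task_cfg: TaskConfig, config: RHebbConfig,
                rng: np.random.Generator) -> TrainingRecord:
    """Train by node perturbation: kick-driven eligibility, end-of-trial
    reward-modulated update.

    Reward is R = -|z - target| with z the output unit's rate averaged
    over the response window and target = +/-1 given by the sign of the
    context-relevant coherence; Rbar is tracked per stimulus condition
    (context, d_m, d_c).  Requires nonzero exploration (kicks or state
    noise).  Accuracy is checked on clean validation batches every
    ``eval_every`` trials; training stops at the criterion or the trial
    budget.
    """
    if config.eta > 0 and config.kick_amplitude * config.kick_probability <= 0 \
            and arch.noise_std_rec <= 0:
        raise ValueError("exploration noise sigma must be > 0 for rHebb learning")
    if task_cfg.encoding_mode != "signed_2channel":
        raise ValueError("the rHebb trainer uses the signed two-channel encoding")
    W_init = params.copy()
    T = task_cfg.n_steps
    alpha = arch.alpha
    xbar_tau = config.running_avg_tau or (T * arch.dt)
    const_drive = np.zeros(arch.n_rec)
    if arch.constant_input_units:
        const_drive[list(arch.constant_input_units)] = 1.0
    levels_m = np.asarray(task_cfg.coherence_levels_motion, dtype=float)
    levels_c = np.asarray(task_cfg.coherence_levels_color, dtype=float)
    per_cond = config.reward_avg_scheme == "per_condition_running_mean"
    Rbar = np.zeros((2, len(levels_m), len(levels_c)))
    seen = np.zeros((2, len(levels_m), len(levels_c)), dtype=np.bool_)
    kernel = _get_kernel()
    val_rng = np.random.default_rng(rng.integers(2 ** 31))
    trace = []
    stop = False
    done = 0
    best_acc = -1.0
    best_W = params.W_rec.copy()
    resp_win = max(1, min(config.response_window, T))
    settle = min(config.settle_steps, T - 1)
    while done < config.n_trials and not stop:
        chunk = min(config.eval_every, config.n_trials - done)
        kernel(params.W_rec, params.W_in, params.b_x, const_drive,
               arch.output_unit_index, levels_m, levels_c, chunk, T, alpha,
               task_cfg.noise_std_motion, task_cfg.noise_std_color,
               arch.noise_std_rec, config.kick_probability,
               config.kick_amplitude, arch.dt / xbar_tau, config.eta,
               config.eta_decay_trials or -1.0,
               config.max_dw if config.max_dw is not None else -1.0,
               config.reward_avg_rate, config.superlinear_exponent, settle,
               resp_win, per_cond, Rbar, seen, done,
               int(rng.integers(2 ** 31)))
        done += chunk
        vb = make_batch(task_cfg, config.n_validation, "alternating",
                        np.random.default_rng(val_rng.integers(2 ** 31)))
        acc = accuracy(params, arch, vb,
                       rng=np.random.default_rng(val_rng.integers(2 ** 31)))
        trace.append((done, acc))
        if acc > best_acc:
            best_acc = acc
            best_W = params.W_rec.copy()
        if acc >= config.stop_accuracy:
            stop = True
    # early stopping with restore: node-perturbation learning is
    # non-monotone at this scale, so training ends at the best-validation
    # checkpoint rather than at the trial budget
    params.W_rec[:] = best_W
    if trace:
        trace.append((done, best_acc))
    return TrainingRecord(
        family="rhebb", W_init=W_init, W_last=params.copy(),
        performance_trace=np.array(trace, dtype=float),
        seed=int(task_cfg.seed),
        config={"spec": asdict(config), "stopped_early": stop},
    )
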