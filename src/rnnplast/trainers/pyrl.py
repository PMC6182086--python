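"""REINFORCE actor-critic trainer for the pyrl (gated-unit) family.

Two recurrent networks are trained together:

* a policy network whose three output channels (choice 1, choice 2, stay)
  parameterize a softmax over actions; it maximizes expected reward by the
  likelihood-ratio (REINFORCE) gradient estimator, with the baseline
  network's value prediction subtracted to reduce variance;
* a baseline network that reads the policy network's rates r(t) and action
  probabilities pi(t) and predicts cumulative future reward; it minimizes
  the squared prediction error averaged over time steps.

Rewards: a correct decision earns +1, an incorrect one 0; steps breaking
fixation earn -1 each (none in the default epoch structure, where the
decision is read at the final step).

Only the plasticity-mask-true entries of each network's candidate-path
recurrent matrix change during training; all mask-false recurrent synapses
stay exactly at their initial values, and the gate parameters stay frozen.
Input, readout and offset parameters are also trained (package
convention).  Optimization is adaptive-moment SGD with global-norm
gradient clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..networks import (Architecture, NetworkParameters, simulate_batch,
                        accuracy, _sigmoid)
from ..records import TrainingRecord
from ..tasks import TaskConfig, make_batch
from .common import Adam, clip_global_norm

__all__ = ["PyrlSpec", "pyrl_train", "gru_forward", "gru_backward"]


@dataclass
class PyrlSpec:
    learning_rate: float = 4e-3
    baseline_learning_rate: float = 4e-3
    n_iterations: int = 3000
    batch_size: int = 32
    gradient_clip_norm: float = 1.0
    lambda_omega: float = 1e-5
    entropy_bonus: float = 0.01  # discourages premature policy collapse
    reward_correct: float = 1.0
    reward_incorrect: float = 0.0
    reward_fixation_break: float = -1.0
    stop_accuracy: float = 0.85
    n_validation: int = 500
    eval_every: int = 100


def gru_forward(params: NetworkParameters, arch: Architecture,
                inputs: np.ndarray, rng: np.random.Generator | None = None):
    """Forward pass of the gated recurrent net, caching gate activations.

    Returns (cache, rs, zs): rs are rectified rates (B,T,N), zs the linear
    readout (B,T,N_out); cache holds what the backward pass needs.
    """
    g = params.gates
    B, T, _ = inputs.shape
    N = arch.n_rec
    x = np.zeros((B, N))
    xs = np.empty((B, T, N))
    zgs = np.empty((B, T, N))
    rgs = np.empty((B, T, N))
    cands = np.empty((B, T, N))
    xprevs = np.empty((B, T, N))
    for t in range(T):
        u_t = inputs[:, t, :]
        r_prev = np.maximum(x, 0.0)
        z_g = _sigmoid(u_t @ g.W_z.T + r_prev @ g.U_z.T + g.b_z)
        r_g = _sigmoid(u_t @ g.W_r.T + r_prev @ g.U_r.T + g.b_r)
        noise = (rng.normal(0.0, arch.noise_std_rec, (B, N))
                 if (rng is not None and arch.noise_std_rec > 0) else 0.0)
        cand = u_t @ params.W_in.T + (r_g * r_prev) @ params.W_rec.T \
            + params.b_x + noise
        xprevs[:, t, :] = x
        x = (1.0 - z_g) * x + z_g * cand
        xs[:, t, :] = x
        zgs[:, t, :] = z_g
        rgs[:, t, :] = r_g
        cands[:, t, :] = cand
    rs = np.maximum(xs, 0.0)
    zs = rs @ params.W_out.T + params.b_out
    cache = {"inputs": inputs, "xs": xs, "xprevs": xprevs, "zgs": zgs,
             "rgs": rgs, "cands": cands, "rs": rs}
    return cache, rs, zs


def gru_backward(params: NetworkParameters, arch: Architecture, cache: dict,
                 dzs: np.ndarray) -> dict[str, np.ndarray]:
    """Backward pass through the gated dynamics for the trained parameters.

    Gate parameters are frozen, so only the state gradient flows through
    them; gradients are returned for W_rec (candidate recurrent), W_in,
    b_x, W_out, b_out.
    """
    g = params.gates
    inputs, xs = cache["inputs"], cache["xs"]
    xprevs, zgs, rgs, cands, rs = (cache["xprevs"], cache["zgs"],
                                   cache["rgs"], cache["cands"], cache["rs"])
    B, T, N = xs.shape
    grads = {"W_rec": np.zeros_like(params.W_rec),
             "W_in": np.zeros_like(params.W_in),
             "b_x": np.zeros_like(params.b_x),
             "W_out": np.zeros_like(params.W_out),
             "b_out": np.zeros_like(params.b_out)}
    gx = np.zeros((B, N))
    for t in range(T - 1, -1, -1):
        dz = dzs[:, t, :]
        grads["W_out"] += dz.T @ rs[:, t, :]
        grads["b_out"] += dz.sum(axis=0)
        gx = gx + (dz @ params.W_out) * (xs[:, t, :] > 0)

        x_prev = xprevs[:, t, :]
        r_prev = np.maximum(x_prev, 0.0)
        z_g, r_g, cand = zgs[:, t, :], rgs[:, t, :], cands[:, t, :]
        dcand = gx * z_g
        dz_g = gx * (cand - x_prev)
        dx_prev = gx * (1.0 - z_g)

        h = r_g * r_prev
        grads["W_rec"] += dcand.T @ h
        grads["W_in"] += dcand.T @ inputs[:, t, :]
        grads["b_x"] += dcand.sum(axis=0)
        dh = dcand @ params.W_rec
        dr_g = dh * r_prev
        dr_prev = dh * r_g

        da_z = dz_g * z_g * (1.0 - z_g)
        dr_prev += da_z @ g.U_z
        da_r = dr_g * r_g * (1.0 - r_g)
        dr_prev += da_r @ g.U_r

        gx = dx_prev + dr_prev * (x_prev > 0)
    return grads


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def pyrl_train(policy_params: NetworkParameters,
               baseline_params: NetworkParameters,
               policy_arch: Architecture, baseline_arch: Architecture,
               task_cfg: TaskConfig, spec: PyrlSpec,
               rng: np.random.Generator):
    """Train the policy/baseline pair; returns (policy_record, baseline_record).

    Each iteration samples a fresh trial batch, draws actions from the
    policy softmax at the decision step, scores rewards, and applies the
    REINFORCE gradient with the baseline's value prediction subtracted;
    the baseline is regressed on cumulative reward (squared error over all
    time steps).
    """
    for arch in (policy_arch, baseline_arch):
        if arch.plasticity_mask is None:
            raise ValueError("pyrl training requires a plasticity mask")
    if baseline_arch.n_in != policy_arch.n_rec + policy_arch.n_out:
        raise ValueError("baseline input width must be N_rec + N_out of the policy")
    pol_init = policy_params.copy()
    base_init = baseline_params.copy()
    pol_vec = {"W_rec": policy_params.W_rec, "W_in": policy_params.W_in,
               "b_x": policy_params.b_x, "W_out": policy_params.W_out,
               "b_out": policy_params.b_out}
    base_vec = {"W_rec": baseline_params.W_rec, "W_in": baseline_params.W_in,
                "b_x": baseline_params.b_x, "W_out": baseline_params.W_out,
                "b_out": baseline_params.b_out}
    pol_opt = Adam(lr=spec.learning_rate)
    base_opt = Adam(lr=spec.baseline_learning_rate)
    val_rng = np.random.default_rng(rng.integers(2 ** 31))
    trace = []
    stop = False
    for it in range(spec.n_iterations):
        if spec.learning_rate > 0 or spec.baseline_learning_rate > 0:
            batch = make_batch(task_cfg, spec.batch_size, "random", rng,
                               family="pyrl")
            inputs = batch.inputs_array()
            B, T, _ = inputs.shape
            cache, rs, zs = gru_forward(policy_params, policy_arch, inputs, rng)
            probs = _softmax(zs[:, -1, :])
            u = rng.random(B)
            cum = np.cumsum(probs, axis=1)
            actions = (u[:, None] > cum).sum(axis=1)  # sampled action index
            rew_rows = np.stack([t.reward_schedule[-1] for t in batch])
            rewards = rew_rows[np.arange(B), actions]

            # baseline sees the policy's rates and action probabilities
            pi_t = _softmax(zs)
            base_in = np.concatenate([rs, pi_t], axis=2)
            bcache, _, vs = gru_forward(baseline_params, baseline_arch,
                                        base_in, rng)
            v = vs[:, :, 0]  # (B, T) value prediction per step
            adv = rewards - v[:, -1]

            dzs_pol = np.zeros_like(zs)
            onehot = np.zeros_like(probs)
            onehot[np.arange(B), actions] = 1.0
            dzs_pol[:, -1, :] = (probs - onehot) * adv[:, None] / B
            if spec.entropy_bonus > 0:
                logp = np.log(np.clip(probs, 1e-12, None))
                ent = -(probs * logp).sum(axis=1, keepdims=True)
                dzs_pol[:, -1, :] += spec.entropy_bonus * probs * (logp + ent) / B
            pol_grads = gru_backward(policy_params, policy_arch, cache, dzs_pol)
            if spec.lambda_omega > 0:
                pol_grads["W_rec"] += 2 * spec.lambda_omega * policy_params.W_rec
            pol_grads["W_rec"] *= policy_arch.plasticity_mask
            clip_global_norm(pol_grads, spec.gradient_clip_norm)
            if spec.learning_rate > 0:
                pol_opt.step(pol_vec, pol_grads)
                policy_params.W_rec[:] = np.where(
                    policy_arch.plasticity_mask, policy_params.W_rec,
                    pol_init.W_rec)

            dvs = np.zeros_like(vs)
            dvs[:, :, 0] = 2.0 * (v - rewards[:, None]) / (B * T)
            base_grads = gru_backward(baseline_params, baseline_arch,
                                      bcache, dvs)
            base_grads["W_rec"] *= baseline_arch.plasticity_mask
            clip_global_norm(base_grads, spec.gradient_clip_norm)
            if spec.baseline_learning_rate > 0:
                base_opt.step(base_vec, base_grads)
                baseline_params.W_rec[:] = np.where(
                    baseline_arch.plasticity_mask, baseline_params.W_rec,
                    base_init.W_rec)

        if (it + 1) % spec.eval_every == 0 or it == spec.n_iterations - 1:
            vb = make_batch(task_cfg, spec.n_validation, "alternating",
                            np.random.default_rng(val_rng.integers(2 ** 31)))
            acc = accuracy(policy_params, policy_arch, vb,
                           rng=np.random.default_rng(val_rng.integers(2 ** 31)))
            trace.append((it + 1, acc))
            if acc >= spec.stop_accuracy:
                stop = True
                break
    cfg = {"spec": asdict(spec), "stopped_early": stop}
    pol_rec = TrainingRecord("pyrl_policy", pol_init, policy_params.copy(),
                             np.array(trace, dtype=float),
                             int(task_cfg.seed), cfg)
    base_rec = TrainingRecord("pyrl_baseline", base_init,
                              baseline_params.copy(),
                              np.array(trace, dtype=float),
                              int(task_cfg.seed), cfg)
    return pol_rec, base_rec
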