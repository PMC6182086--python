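"""Leaky-rate recurrent dynamics, the gated-unit variant, readout and lesions.

All model families share the first-order leaky rate equation

    tau dx/dt = -x + W_rec r + W_in u + b_x + rho_x,   r = f(x),

discretized with an explicit Euler step of size dt (alpha = dt / tau):

    x[t] = (1 - alpha) x[t-1] + alpha (W_rec r[t-1] + W_in u[t] + b_x + rho),

with f = tanh for the HF and rHebb families and f = rectified linear for
pycog.  The pyrl family replaces the leaky step with a two-gate (update /
reset) recurrent unit.  Readout is linear, z = W_out r + b_z; the rHebb
family instead reads its output from the rate of one designated recurrent
unit.  Per-step state noise rho_x is Gaussian with a per-family sigma; it
is added inside the driven term, so its stationary effect scales with
alpha like the other drives.

Unit inactivation clamps selected units at every step of the recurrent
loop: ``zero_output`` forces the unit's rate to 0; ``bias_constant`` (HF)
pins the unit's potential at its offset b_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .tasks import CHOICE1, CHOICE2, STAY, TrialBatch, Trial

__all__ = [
    "Architecture",
    "NetworkParameters",
    "GateParameters",
    "StateTrajectory",
    "InactivationSpec",
    "InitSpec",
    "default_architecture",
    "default_init",
    "init_parameters",
    "step_leaky",
    "step_gated",
    "run_trial",
    "simulate_batch",
    "decode_choice",
    "decode_choices_batch",
    "accuracy",
]


@dataclass(frozen=True)
class Architecture:
    """Static description of one model instance's network."""

    family: Literal["hf", "pycog", "pyrl_policy", "pyrl_baseline", "rhebb"]
    n_in: int
    n_rec: int
    n_out: int
    activation: Literal["tanh", "rectified_linear"]
    tau: float = 10.0
    dt: float = 1.0
    noise_std_rec: float = 0.004
    dale_signs: np.ndarray | None = None  # (+1 excitatory / -1 inhibitory) per unit
    plasticity_mask: np.ndarray | None = None  # boolean over recurrent synapses
    output_unit_index: int = 0  # rHebb only
    constant_input_units: tuple = ()  # rHebb only: units with +1 constant drive

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    def activate(self, x: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            return np.tanh(x)
        return np.maximum(x, 0.0)

    def activate_deriv(self, x: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            return 1.0 - np.tanh(x) ** 2
        return (x > 0.0).astype(float)


@dataclass
class GateParameters:
    """Update/reset gate parameters of the gated recurrent unit (pyrl)."""

    W_z: np.ndarray
    U_z: np.ndarray
    b_z: np.ndarray
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray

    def copy(self) -> "GateParameters":
        return GateParameters(*(m.copy() for m in
                                (self.W_z, self.U_z, self.b_z,
                                 self.W_r, self.U_r, self.b_r)))


@dataclass
class NetworkParameters:
    """Weight matrices and offsets of one network instance.

    Row index of ``W_rec`` is the postsynaptic unit, column index the
    presynaptic unit.  ``W_out``/``b_out`` are absent (None) for the rHebb
    family, whose output is a designated recurrent unit.
    """

    W_rec: np.ndarray
    W_in: np.ndarray
    b_x: np.ndarray
    W_out: np.ndarray | None = None
    b_out: np.ndarray | None = None
    gates: GateParameters | None = None

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            W_rec=self.W_rec.copy(),
            W_in=self.W_in.copy(),
            b_x=self.b_x.copy(),
            W_out=None if self.W_out is None else self.W_out.copy(),
            b_out=None if self.b_out is None else self.b_out.copy(),
            gates=None if self.gates is None else self.gates.copy(),
        )

    def check_shapes(self, arch: Architecture) -> None:
        N, Ni, No = arch.n_rec, arch.n_in, arch.n_out
        if self.W_rec.shape != (N, N):
            raise ValueError(f"W_rec shape {self.W_rec.shape} != ({N},{N})")
        if self.W_in.shape != (N, Ni):
            raise ValueError(f"W_in shape {self.W_in.shape} != ({N},{Ni})")
        if self.b_x.shape != (N,):
            raise ValueError("b_x shape mismatch")
        if self.W_out is not None and self.W_out.shape != (No, N):
            raise ValueError("W_out shape mismatch")


@dataclass
class StateTrajectory:
    x: np.ndarray  # (T, N_rec) membrane potentials
    r: np.ndarray  # (T, N_rec) rates
    z: np.ndarray  # (T, N_out) outputs
    choice: int | None = None
    tie_broken: bool = False


@dataclass(frozen=True)
class InactivationSpec:
    unit_indices: tuple
    clamp_mode: Literal["zero_output", "bias_constant"] = "zero_output"

    def validate(self, arch: Architecture) -> None:
        idx = np.asarray(self.unit_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= arch.n_rec):
            raise ValueError("inactivation indices out of range")
        if self.clamp_mode == "bias_constant" and arch.family != "hf":
            raise ValueError("bias_constant clamping is defined for the HF family only")


@dataclass(frozen=True)
class InitSpec:
    """Initial weight distribution.

    ``gaussian``: i.i.d. N(mu, sigma^2).
    ``gamma``: magnitudes ~ Gamma(K, theta); the sign of each column
      (presynaptic unit) is the unit's Dale sign if the architecture has
      one, else a random +/-1 per column.
    ``uniform``: i.i.d. U(a, b) magnitudes with the same column-sign rule.
    """

    kind: Literal["gaussian", "gamma", "uniform"] = "gaussian"
    mu: float = 0.0
    sigma: float = 0.01
    K: float = 4.0
    theta: float = 0.01
    a: float = 0.0
    b: float = 1.0


# ---------------------------------------------------------------------------
# default architectures (full-scale sizes: HF 4/100/1, pycog 6/150/2 with a
# 4:1 excitatory:inhibitory split, pyrl 6/100/3 + baseline 103/100/1,
# rHebb 4/200/1)

def default_architecture(family: str, n_rec: int | None = None,
                         seed: int = 0) -> Architecture:
    """Default architecture for a family, optionally resized.

    Sizes default to the full-scale settings; ``n_rec`` rescales the
    recurrent population (the pycog excitatory:inhibitory ratio and the
    pyrl 10% plasticity density are preserved).
    """
    rng = np.random.default_rng(seed)
    if family == "hf":
        N = n_rec or 100
        return Architecture("hf", 4, N, 1, "tanh", tau=10.0, dt=1.0,
                            noise_std_rec=0.004)
    if family == "rhebb":
        N = n_rec or 200
        # units 1..3 receive a constant +1 drive; unit 0 is the readout
        return Architecture("rhebb", 4, N, 1, "tanh", tau=30.0, dt=1.0,
                            noise_std_rec=0.004, output_unit_index=0,
                            constant_input_units=(1, 2, 3))
    if family == "pycog":
        N = n_rec or 150
        n_exc = int(round(N * 0.8))
        signs = np.ones(N)
        signs[n_exc:] = -1.0
        return Architecture("pycog", 6, N, 2, "rectified_linear", tau=10.0,
                            dt=1.0, noise_std_rec=0.004, dale_signs=signs)
    if family in ("pyrl_policy", "pyrl_baseline"):
        N = n_rec or 100
        # exactly 10% of recurrent synapses are plastic
        n_plastic = int(round(0.10 * N * N))
        flat = np.zeros(N * N, dtype=bool)
        flat[rng.choice(N * N, size=n_plastic, replace=False)] = True
        mask = flat.reshape(N, N)
        if family == "pyrl_policy":
            return Architecture("pyrl_policy", 6, N, 3, "rectified_linear",
                                tau=10.0, dt=1.0, noise_std_rec=0.004,
                                plasticity_mask=mask)
        return Architecture("pyrl_baseline", N + 3, N, 1, "rectified_linear",
                            tau=10.0, dt=1.0, noise_std_rec=0.004,
                            plasticity_mask=mask)
    raise ValueError(f"unknown family {family!r}")


def default_init(family: str, arch: Architecture) -> InitSpec:
    """Per-family default initial recurrent-weight distribution.

    HF: N(0, 0.15) -- the alternative initialization also used at full
    scale; the historical N(0, 0.01) initialization leaves the recurrent
    gain too weak for first-order gradient descent (it was paired with a
    curvature-based solver) and is available via an explicit InitSpec.
    rHebb: N(0, g / sqrt(N)) with gain g = 1.5, which gives the stated
    sigma = 0.106 at N = 200.  pycog / pyrl: Gamma(K=4) magnitudes with
    Dale-sign (pycog) or random-sign (pyrl) column multipliers, scaled so
    columns balance.
    """
    if family == "hf":
        return InitSpec("gaussian", 0.0, 0.15)
    if family == "rhebb":
        return InitSpec("gaussian", 0.0, 1.5 / np.sqrt(arch.n_rec))
    if family == "pycog":
        return InitSpec("gamma", K=4.0, theta=0.075 / np.sqrt(arch.n_rec))
    return InitSpec("gamma", K=4.0, theta=0.25 / np.sqrt(arch.n_rec))


def init_parameters(arch: Architecture, init_spec: InitSpec,
                    rng: np.random.Generator) -> NetworkParameters:
    """Draw initial parameters for an architecture.

    The recurrent matrix follows ``init_spec``; input and readout weights
    are modest Gaussians.  For the pycog family, inhibitory columns of the
    recurrent matrix are rescaled by the excitatory:inhibitory count ratio
    so total excitation and inhibition balance, and signs conform to the
    Dale vector.  Gated architectures get random small gate parameters.
    """
    N, Ni, No = arch.n_rec, arch.n_in, arch.n_out

    def draw_rec() -> np.ndarray:
        if init_spec.kind == "gaussian":
            if init_spec.sigma <= 0:
                raise ValueError("sigma must be positive")
            return rng.normal(init_spec.mu, init_spec.sigma, (N, N))
        if init_spec.kind == "gamma":
            if init_spec.K <= 0 or init_spec.theta <= 0:
                raise ValueError("gamma parameters must be positive")
            mag = rng.gamma(init_spec.K, init_spec.theta, (N, N))
        elif init_spec.kind == "uniform":
            mag = rng.uniform(init_spec.a, init_spec.b, (N, N))
        else:
            raise ValueError(f"unknown init kind {init_spec.kind!r}")
        if arch.dale_signs is not None:
            signs = arch.dale_signs.copy()
            n_exc = int(np.sum(signs > 0))
            n_inh = N - n_exc
            W = mag * signs[None, :]
            if n_inh > 0:  # balance total excitation against inhibition
                W[:, signs < 0] *= n_exc / n_inh
        else:
            signs = rng.choice([-1.0, 1.0], size=N)
            W = mag * signs[None, :]
        return W

    W_rec = draw_rec()
    if arch.family == "hf":
        W_in = rng.normal(0.0, init_spec.sigma, (N, Ni))
        W_out = rng.normal(0.0, init_spec.sigma, (No, N))
        return NetworkParameters(W_rec, W_in, np.zeros(N), W_out, np.zeros(No))
    if arch.family == "rhebb":
        W_in = rng.normal(0.0, 0.5, (N, Ni))
        return NetworkParameters(W_rec, W_in, np.zeros(N))
    if arch.family == "pycog":
        W_in = rng.normal(0.0, 1.0 / np.sqrt(Ni), (N, Ni))
        W_out = rng.normal(0.0, 1.0 / np.sqrt(N), (No, N))
        return NetworkParameters(W_rec, W_in, np.full(N, 0.1), W_out, np.zeros(No))
    # gated (pyrl) families
    W_in = rng.normal(0.0, 1.0 / np.sqrt(Ni), (N, Ni))
    W_out = rng.normal(0.0, 1.0 / np.sqrt(N), (No, N))
    s = 1.0 / np.sqrt(N)
    # update-gate bias set so the gate opens at alpha = dt/tau on average,
    # giving the gated units the same leak time constant as the other
    # families instead of the ~2-step memory of a zero-bias gate
    a = arch.alpha
    gates = GateParameters(
        W_z=rng.normal(0.0, 1.0 / np.sqrt(Ni), (N, Ni)),
        U_z=rng.normal(0.0, s, (N, N)),
        b_z=np.full(N, np.log(a / (1.0 - a))),
        W_r=rng.normal(0.0, 1.0 / np.sqrt(Ni), (N, Ni)),
        U_r=rng.normal(0.0, s, (N, N)),
        b_r=np.zeros(N),
    )
    return NetworkParameters(W_rec, W_in, np.zeros(N), W_out, np.zeros(No), gates)


# ---------------------------------------------------------------------------
# dynamics

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def step_leaky(params: NetworkParameters, arch: Architecture,
               x_prev: np.ndarray, u_t: np.ndarray,
               noise: np.ndarray | float = 0.0) -> np.ndarray:
    """One explicit-Euler step of the leaky rate equation.

    Works on a single state vector (N,) or a batch (B, N); ``u_t`` matches
    on the leading axis.
    """
    a = arch.alpha
    r_prev = arch.activate(x_prev)
    drive = r_prev @ params.W_rec.T + u_t @ params.W_in.T + params.b_x + noise
    x_next = (1.0 - a) * x_prev + a * drive
    if not np.all(np.isfinite(x_next)):
        raise FloatingPointError("non-finite network state")
    return x_next


def step_gated(params: NetworkParameters, arch: Architecture,
               x_prev: np.ndarray, u_t: np.ndarray,
               noise: np.ndarray | float = 0.0) -> np.ndarray:
    """One step of the two-gate (update/reset) recurrent unit.

    With both gates forced to 1 this reduces to the unleaky recurrent step
    x = W_rec r_prev + W_in u + b_x; with the update gate at 0 the state is
    frozen.  ``W_rec`` plays the role of the candidate-path recurrent
    matrix.
    """
    g = params.gates
    if g is None:
        raise ValueError("gate_parameters required for gated step")
    r_prev = arch.activate(x_prev)
    z_g = _sigmoid(u_t @ g.W_z.T + r_prev @ g.U_z.T + g.b_z)
    r_g = _sigmoid(u_t @ g.W_r.T + r_prev @ g.U_r.T + g.b_r)
    cand = u_t @ params.W_in.T + (r_g * r_prev) @ params.W_rec.T + params.b_x + noise
    x_next = (1.0 - z_g) * x_prev + z_g * cand
    if not np.all(np.isfinite(x_next)):
        raise FloatingPointError("non-finite network state")
    return x_next


def _clamped_rates(x: np.ndarray, arch: Architecture, params: NetworkParameters,
                   spec: InactivationSpec | None) -> np.ndarray:
    r = arch.activate(x)
    if spec is None or not len(spec.unit_indices):
        return r
    idx = list(spec.unit_indices)
    r = r.copy()
    if spec.clamp_mode == "zero_output":
        r[..., idx] = 0.0
    else:  # bias_constant: potential fixed at the unit's offset b_x
        r[..., idx] = arch.activate(params.b_x[idx])
    return r


def simulate_batch(params: NetworkParameters, arch: Architecture,
                   inputs: np.ndarray, rng: np.random.Generator | None = None,
                   inactivation: InactivationSpec | None = None,
                   return_states: bool = False):
    """Run a batch of trials; ``inputs`` is (B, T, N_in).

    Returns (xs, rs, zs) with shapes (B, T, N), (B, T, N), (B, T, N_out).
    Clamped units are overridden at every step, so their rates never feed
    the recurrent loop or the readout.
    """
    if inactivation is not None:
        inactivation.validate(arch)
    B, T, Ni = inputs.shape
    if Ni != arch.n_in:
        raise ValueError(f"input width {Ni} != N_in {arch.n_in}")
    N = arch.n_rec
    gated = params.gates is not None
    a = arch.alpha
    const_drive = np.zeros(N)
    if arch.constant_input_units:
        const_drive[list(arch.constant_input_units)] = 1.0

    x = np.zeros((B, N))
    xs = np.empty((B, T, N))
    rs = np.empty((B, T, N))
    for t in range(T):
        noise = (rng.normal(0.0, arch.noise_std_rec, (B, N))
                 if (rng is not None and arch.noise_std_rec > 0) else 0.0)
        r_prev = _clamped_rates(x, arch, params, inactivation)
        u_t = inputs[:, t, :]
        if gated:
            g = params.gates
            z_g = _sigmoid(u_t @ g.W_z.T + r_prev @ g.U_z.T + g.b_z)
            r_g = _sigmoid(u_t @ g.W_r.T + r_prev @ g.U_r.T + g.b_r)
            cand = (u_t @ params.W_in.T + (r_g * r_prev) @ params.W_rec.T
                    + params.b_x + const_drive + noise)
            x = (1.0 - z_g) * x + z_g * cand
        else:
            drive = (r_prev @ params.W_rec.T + u_t @ params.W_in.T
                     + params.b_x + const_drive + noise)
            x = (1.0 - a) * x + a * drive
        if inactivation is not None and inactivation.clamp_mode == "bias_constant" \
                and len(inactivation.unit_indices):
            idx = list(inactivation.unit_indices)
            x[:, idx] = params.b_x[idx]
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite network state during simulation")
        xs[:, t, :] = x
        rs[:, t, :] = _clamped_rates(x, arch, params, inactivation)

    if arch.family == "rhebb":
        zs = rs[:, :, [arch.output_unit_index]]
    else:
        zs = rs @ params.W_out.T + params.b_out
    return xs, rs, zs


def run_trial(params: NetworkParameters, arch: Architecture, trial: Trial,
              inactivation: InactivationSpec | None = None,
              rng: np.random.Generator | None = None) -> StateTrajectory:
    """Simulate a single trial and decode its choice."""
    xs, rs, zs = simulate_batch(params, arch, trial.inputs[None], rng, inactivation)
    traj = StateTrajectory(x=xs[0], r=rs[0], z=zs[0])
    traj.choice, traj.tie_broken = _decode(zs[0, -1], arch.family)
    return traj


def _decode(z_final: np.ndarray, family: str) -> tuple[int, bool]:
    if family in ("hf", "rhebb"):
        v = float(z_final[0])
        if v == 0.0:
            return CHOICE1, True
        return (CHOICE1 if v > 0 else CHOICE2), False
    if family == "pycog":
        tie = z_final[0] == z_final[1]
        return (CHOICE1 if z_final[0] >= z_final[1] else CHOICE2), bool(tie)
    if family in ("pyrl_policy", "pyrl"):
        # channels ordered (choice1, choice2, stay); lowest index wins ties
        k = int(np.argmax(z_final))
        tie = bool(np.sum(z_final == z_final[k]) > 1)
        return ((CHOICE1, tie) if k == 0 else
                (CHOICE2, tie) if k == 1 else (STAY, tie))
    raise ValueError(f"unknown family {family!r}")


def decode_choice(traj: StateTrajectory, family: str) -> int:
    choice, _ = _decode(traj.z[-1], family)
    return choice


def decode_choices_batch(zs: np.ndarray, family: str) -> np.ndarray:
    """Vectorized decoding of final-step outputs, (B, T, N_out) -> (B,)."""
    zf = zs[:, -1, :]
    if family in ("hf", "rhebb"):
        return np.where(zf[:, 0] >= 0, CHOICE1, CHOICE2)
    if family == "pycog":
        return np.where(zf[:, 0] >= zf[:, 1], CHOICE1, CHOICE2)
    if family in ("pyrl_policy", "pyrl"):
        k = np.argmax(zf, axis=1)
        out = np.full(len(k), STAY)
        out[k == 0] = CHOICE1
        out[k == 1] = CHOICE2
        return out
    raise ValueError(f"unknown family {family!r}")


def accuracy(params: NetworkParameters, arch: Architecture, batch: TrialBatch,
             inactivation: InactivationSpec | None = None,
             rng: np.random.Generator | None = None) -> float:
    """Fraction of correctly decoded choices over a batch.

    Trials whose context-relevant coherence is zero are excluded (their
    correct answer is undefined)."""
    keep = [t for t in batch
            if (t.d_m if t.context == "motion" else t.d_c) != 0]
    if not keep:
        raise ValueError("no scorable trials in batch")
    inputs = np.stack([t.inputs for t in keep])
    _, _, zs = simulate_batch(params, arch, inputs, rng, inactivation)
    decoded = decode_choices_batch(zs, arch.family)
    truth = np.array([t.correct_choice for t in keep])
    return float(np.mean(decoded == truth))
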