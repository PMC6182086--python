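# Methods

## Models

All four families simulate discrete-time leaky rate dynamics by explicit
first-order Euler steps with α = dt/τ:

    x[t] = (1 − α) x[t−1] + α (W_rec r[t−1] + W_in u[t] + b_x + ρ_x[t]),
    r[t] = f(x[t]),

with f = tanh for the HF and rHebb families and f = max(x, 0) for pycog.
State noise ρ_x is drawn per step at the configured σ and added inside the
driven term (no √dt scaling: the σ values are defined per step).  Readout
is linear, z = W_out r + b_z; the rHebb family instead reads the rate of
one designated recurrent unit (unit 0 by default) and gives three further
units a constant +1 drive.  The pyrl family replaces the leaky step with a
standard two-gate (update/reset) recurrent unit; with both gates forced
to 1 it reduces to the unleaky recurrent step, and the frozen update-gate
bias is initialized at σ⁻¹(dt/τ) so the gated units start with the same
leak time constant as the other families instead of the ~2-step memory a
zero bias would give.

Choices are decoded from the final step: sign of the scalar output
(HF, rHebb), argmax of two channels (pycog), argmax of three channels
including "stay" (pyrl); exact ties go to the lowest channel index and
are flagged.

## Task

Each trial presents constant signed offsets d_m, d_c plus i.i.d. Gaussian
noise on the sensory channels and a one-hot binary context pair; the
correct choice is the sign of the context-relevant coherence, and
zero-coherence trials are excluded from accuracy scoring because their
correct answer is undefined.  Two encodings carry the same information:
signed two-channel (tanh families) and separated four-channel, ordered
[motion-right, motion-left, color-red, color-green] with value = baseline
(0.2) + |d| on the favored channel (rectified families).

Default stimulus statistics for the HF, pycog and pyrl families: 30 ms
trials at dt = 1 ms, τ = 10 ms, sensory noise σ = 0.04 per modality,
state noise σ = 0.004, and six symmetric coherence levels
±{0.01, 0.02, 0.04} per modality (the level set is a package convention:
multiple levels are needed for psychometric behavior, and the magnitudes
are capped at the stated offset scale).  Targets: HF scores a scalar
target (0 at the first step, ±1 at the last) at exactly those two time
points; pycog scores a two-channel one-hot target at the final step only
(the error mask is false elsewhere, and the loss divides by the full T
as well as N_out); pyrl earns +1 for a correct decision, 0 for an
incorrect one, and −1 per fixation-break step (no fixation epoch is
configured by default, so the decision is read at the final step).

The rHebb family runs the same task at its native stimulus regime:
500 ms trials, τ = 30 ms, coherences ±{0.25, 0.5, 1.0}, sensory noise
σ = 0.1.  The signal-to-noise ratios match the other families' set; the
absolute scale is the one the node-perturbation rule was designed around,
where stimulus drive is comparable to recurrent activity.  At the 0.04
scale the stimulus is invisible next to O(1) recurrent fluctuations and
the rule receives no usable gradient signal (measured: chance performance
at any learning rate).

## Trainers

**HF.**  Adam on L = (1/2N) Σ_n Σ_{t∈{0,T}} (z − z*)², gradients by
backpropagation through time, global-norm clipping at 1.0.  The
curvature-based (Hessian-free) solver with structural damping is not
implemented; the objective — not the second-order optimizer — defines the
family, and the damping penalty is off by default.  Because first-order
descent cannot escape the weak-gain regime of the historical N(0, 0.01)
initialization (measured: ~75% plateau after 8000 iterations), the
default initialization is N(0, 0.15), the alternative initialization also
examined at full scale, which reaches the performance criterion in ~1000
iterations.  N(0, 0.01) remains available through `InitSpec`.

**pycog.**  Adam on the masked mean-squared error plus λ_Ω·‖W_rec‖²
(λ_Ω = 1e−4).  The cited vanishing-gradient regularizer is replaced by
this plain L2 penalty: at 30-step trials gradients do not vanish, and the
exact coefficients were never published.  Dale's law is enforced by
projection after every update — entries whose sign violates their
presynaptic column's type are clipped to zero (idempotent).  Initial
weights are Gamma(K = 4) magnitudes signed by column type, with
inhibitory columns scaled by the E:I count ratio so total excitation and
inhibition balance.

**pyrl.**  REINFORCE with a learned baseline.  The policy samples an
action from the softmax of its final-step outputs; the gradient of
−E[R] is estimated with the advantage R − v, where the baseline network
(input: the policy's rates and action probabilities, width N_rec + 3)
predicts cumulative reward and is regressed on it over all time steps.
Both networks train with Adam and gradient clipping, and the policy
gradient carries a small entropy bonus (0.01) that discourages premature
collapse onto one action -- without it a sizeable fraction of seeds
plateaus near 70%.  Exactly 10% of each
network's candidate-path recurrent synapses are plastic (an exact-count
random mask); all other recurrent and gate parameters stay frozen at
their initial values — mask-false entries are restored exactly after
every update, so the frozen-synapse identity is exact, not approximate.
Input, readout and offset parameters are also trained (package
convention; with a frozen random readout the reduced-scale network cannot
reach the performance bar).

**rHebb.**  Node perturbation: sparse strong kicks (per-unit probability
0.003 per step, amplitude uniform ±0.5) injected into the potentials
drive exploration; every step each synapse accumulates
e_ij += (r_j(t−1)·(x_i(t) − x̄_i))³ where x̄ is an exponential running
average with a 5 ms time constant, updated before use; accumulation
starts after a 100-step settling window so the trial-onset transient does
not contaminate the trace.  The response is the output unit's rate
averaged over the last 50 steps, the reward is R = −|z − target| with
target ±1, and at trial end ΔW = η e (R − R̄) with the per-condition
reward baseline R̄ (EMA rate 0.5 over repeats of the same (context, d_m,
d_c) condition; the first visit only initializes R̄).  Updates are
clipped elementwise at 2e−4; η = 0.25 decays as 1/(1 + trial/15000).
Because learning under this rule is non-monotone at reduced scale,
training returns the best-validation checkpoint (early stopping with
restore).  The trial loop is compiled with numba; the pure-numpy
`rhebb_accumulate`/`rhebb_apply` operations define the reference
semantics and are tested against brute-force per-synapse loops.

All trainers snapshot the initial parameters before any update, generate
fresh trials every iteration, stop at ≥ 85% validation accuracy on a
500-trial batch or at their budget, and are bit-reproducible from their
seeds.

## Analysis

Post-mean weights and changes are row means of absolute values over the
analyzed population; rows are postsynaptic (the prose convention of the
eligibility rule is the transpose of its formula — the formula, which
matches the post-mean definition, is followed).  Analysis populations:
all units (HF), excitatory→excitatory (pycog; 120 post units at full
scale), all units excluding the output and three constant-input units
(rHebb; 196 at full scale), and the plastic 10% of synapses (pyrl; 1,000
elements at full scale).  For the element-masked pyrl population the
post-mean divides by each unit's count of analyzed presynapses — a mean
over the analyzed population rather than over all recurrent units
(flagged interpretation; the alternative divisor only rescales rows).
Ranking is by descending post-mean change with ties broken by unit index.

Distribution shape: Shapiro–Wilk normality, D'Agostino-type skewness and
kurtosis Z-tests (scipy's `skewtest`/`kurtosistest`), kurtosis reported
as excess kurtosis (normal = 0), biased moment estimators (scipy
defaults).  Samples need n ≥ 8 and nonzero spread.

## Perturbation experiments

Inactivation clamps units at every recurrent step: rate forced to 0, or,
for the HF family, potential pinned at the unit's offset b_x.  Sweeps run
over sort order (descending / ascending / shuffled by post-mean change) ×
lesion count (steps of 10 over the analyzed population — excitatory units
only for pycog) × system replicate.  One evaluation batch is drawn per
(system, lesion size) and shared across orders, so order comparisons are
paired and the zero-lesion cell equals the unlesioned baseline exactly
(deviation from the per-cell-batch design, chosen for exactness of that
identity and lower comparison variance).  Accuracy per cell uses 200
evaluation trials by default.  The factorial grid feeds a fixed-effects
two-way ANOVA with interaction (statsmodels OLS/anova_lm; dfs are exact
functions of the design) and Tukey-HSD pairwise order comparisons at each
lesion size (scipy).  Size sweeps retrain per (size, seed) through an
injected training function, score accuracy and post-mean-change skewness,
and compare sizes with Kruskal–Wallis plus a hand-implemented Dunn's test
(rank z-statistics with tie correction, Holm adjustment) — implemented
here because no installed package provides it.

## Synthetic fixtures

Planted-plasticity fixtures draw W_init from N(0, 0.1²) and weight
changes row-wise: k "hot" postsynaptic rows at σ_hot, the rest at σ_bg
(Gaussian rather than heavy-tailed draws — the simplest generative
structure with row-localized changes).  They emulate only the weight
structure the analysis assumes, not temporal activity, training dynamics,
or any relation between weights and behavior; tests that pass on fixtures
validate the analysis pipeline, not the training claims.  A k = 0 fixture
is the null control for skew-test calibration.

## Study conditions and what the tests show

Reduced-scale conditions, with the task settings above: performance-bar
checks train with each family's defaults (N_rec = 50 for HF/pycog/pyrl,
64 for rHebb; training stops at 85% validation accuracy) and evaluate on
fresh 500-trial batches.  All four families clear the bar within minutes
on one CPU; the node-perturbation family needs its best-validation
checkpoint and the constant-input bias units to do so.

The localization and lesion experiments use five seeds per family.  The
HF and pycog study systems are trained at N_rec = 100 to a 0.97
validation criterion: systems stopped right at the 85% bar have no
performance margin and collapse to near-chance under any 10-unit lesion,
which hides the sort-order contrast; converged systems reproduce the
expected pattern (clamping the most plastic units first is catastrophic
while the reverse order degrades gracefully).  The pyrl study systems
keep the default batch-32 / 85%-stop settings — training the policy
longer or with larger batches visibly spreads the plastic changes across
units and weakens the post-mean skew, itself an instructive observation:
the localization signature is a property of noisy, just-sufficient
learning.  The skew signature appears robustly across seeds in all four
families at these conditions.

## Known limitations

* The curvature-based HF optimizer and Levenberg–Marquardt λ adaptation
  are not implemented (gradient descent on the same objective instead).
* The structural-damping penalty is a stub (off by default).
* Exact full-scale statistic values (test Z/p magnitudes at N = 100–200
  with the original trial budgets) are not desk-scale reproducible; the
  package reproduces the qualitative findings and the exact structural
  quantities (population counts, ANOVA dfs).
* The pyrl fixation epoch is not configured by default, so fixation-break
  rewards never occur in the default conditions.
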