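"""Generate context-dependent integration trials and inspect their structure.

Each trial presents noisy motion and color evidence plus a binary context
cue; the correct choice is the sign of the context-relevant coherence.
"""

import numpy as np

from rnnplast import make_batch
from rnnplast.presets import scaled_task_config

cfg = scaled_task_config("hf", seed=1)
batch = make_batch(cfg, 6, "alternating", np.random.default_rng(1))

print(f"{batch.n_trials} trials, {cfg.n_steps} steps of {cfg.dt} ms each, "
      f"{cfg.n_in} input channels ({cfg.encoding_mode})")
for t in batch:
    rel = t.d_m if t.context == "motion" else t.d_c
    print(f"  context={t.context:6s} d_m={t.d_m:+.2f} d_c={t.d_c:+.2f} "
          f"-> relevant {rel:+.2f}, correct choice {t.correct_choice}")
# channel means approximate the offsets; the per-step noise has sigma 0.04
print("channel means of trial 0:", np.round(batch.trials[0].inputs.mean(0), 3))
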