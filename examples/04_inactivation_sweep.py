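"""Lesion trained networks in plasticity-ranked order.

Trains two small pycog-family networks, then clamps growing numbers of
units to zero output -- starting from the most plastic (descending), the
least plastic (ascending), or a shuffled order -- and compares accuracy.
If high-plasticity units carry the behavior, descending lesions should
hurt more.
"""

import numpy as np

from rnnplast.perturbation import (posthoc_pairwise, run_inactivation_sweep,
                                   two_way_anova)
from rnnplast.presets import scaled_task_config, train_family

records, archs = [], []
for seed in (1, 2):
    rec, arch = train_family("pycog", seed=seed)
    print(f"seed {seed}: accuracy {rec.final_accuracy:.3f}")
    records.append(rec)
    archs.append(arch)

cfg = scaled_task_config("pycog", seed=99)
sweep = run_inactivation_sweep(records, archs, cfg,
                               grid=np.arange(0, 41, 10),
                               rng=np.random.default_rng(0))
print(sweep.to_frame().pivot_table(index="n_inact", columns="sort_type",
                                   values="accuracy").round(3))
print(two_way_anova(sweep).round(3).to_string(index=False))
post = posthoc_pairwise(sweep)
print(post[post.pair == "descending-ascending"].round(3).to_string(index=False))
# negative mean_diff at intermediate n = descending lesions degrade more
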