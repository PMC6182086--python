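"""Train one HF-family network and locate where learning put the changes.

Trains a reduced-scale tanh network by gradient descent on the two-point
squared-error objective, then computes post-mean weight changes per
postsynaptic unit and tests the distribution for positive skew -- the
signature of plasticity concentrated on a small neuronal population.
"""

import numpy as np

from rnnplast import summarize_model
from rnnplast.presets import train_family

record, arch = train_family("hf", seed=1)
print(f"validation accuracy after training: {record.final_accuracy:.3f}")

summary = summarize_model(record, arch)
st = summary.postmean_diff_stats
print(f"post-mean weight change over {st.n} units: "
      f"skewness {st.skewness:.2f} (Z = {st.skew_z:.2f}, p = {st.skew_p:.2g})")
print(f"element-level changes (n = {summary.element_diff_stats.n}): "
      f"excess kurtosis {summary.element_diff_stats.kurtosis_excess:.2f}")
top = summary.mask.included_post_units[summary.ranking[:5]]
print("most plastic units:", top.tolist())
# positive skew + heavy tails = changes localized to few units/synapses
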