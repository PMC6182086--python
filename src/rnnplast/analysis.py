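"""Weight-change localization statistics.

The central quantities are the per-postsynaptic-unit means of absolute
synaptic weights and weight changes:

    Wbar_i^last = (1/N) sum_j |W_ij^last|          (post-mean weight)
    Wbar_i^diff = (1/N) sum_j |W_ij^diff|,         (post-mean weight change)
    W_ij^diff   = W_ij^last - W_ij^init,

with i the postsynaptic (row) and j the presynaptic (column) unit.  A
heavily right-skewed distribution of Wbar^diff across units means learning
concentrated its changes on a small neuronal population.

Which synapses enter the analysis depends on the family: all recurrent
synapses (HF), excitatory-to-excitatory only (pycog), the plastic 10%
(pyrl policy), or all units except the output and constant-input units
(rHebb).  Distribution shape is assessed with the Shapiro-Wilk normality
test and the D'Agostino-type skewness and kurtosis Z-tests; kurtosis is
reported as excess kurtosis (normal = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .networks import Architecture
from .records import TrainingRecord

__all__ = [
    "AnalysisMask",
    "WeightChangeSummary",
    "DistributionStats",
    "build_mask",
    "weight_diff",
    "post_mean",
    "rank_units",
    "dist_stats",
    "summarize_model",
    "default_policy",
]

_POLICIES = ("all", "E_E_only", "exclude_output_and_constant", "plastic_only")


@dataclass
class AnalysisMask:
    """Which post/pre units (and optionally which elements) are analyzed."""

    included_post_units: np.ndarray
    included_pre_units: np.ndarray
    rationale: str
    element_mask: np.ndarray | None = None  # over the full W_rec shape

    def __post_init__(self):
        if len(self.included_post_units) == 0 or len(self.included_pre_units) == 0:
            raise ValueError("analysis mask must include at least one unit")

    @property
    def n_post(self) -> int:
        return len(self.included_post_units)

    def submatrix(self, M: np.ndarray) -> np.ndarray:
        return M[np.ix_(self.included_post_units, self.included_pre_units)]

    def sub_element_mask(self) -> np.ndarray | None:
        if self.element_mask is None:
            return None
        return self.element_mask[np.ix_(self.included_post_units,
                                        self.included_pre_units)]

    def elements(self, M: np.ndarray) -> np.ndarray:
        """Flattened analyzed elements of a recurrent matrix."""
        sub = self.submatrix(M)
        em = self.sub_element_mask()
        return sub[em] if em is not None else sub.ravel()


@dataclass
class DistributionStats:
    n: int
    normality_W: float
    normality_p: float
    skewness: float
    skew_z: float
    skew_p: float
    kurtosis_excess: float
    kurt_z: float
    kurt_p: float


@dataclass
class WeightChangeSummary:
    mask: AnalysisMask
    W_diff: np.ndarray
    post_mean_last: np.ndarray
    post_mean_diff: np.ndarray
    ranking: np.ndarray  # post units (indices into included_post_units order)
    postmean_last_stats: DistributionStats
    postmean_diff_stats: DistributionStats
    element_diff_stats: DistributionStats


def default_policy(family: str) -> str:
    return {"hf": "all", "pycog": "E_E_only",
            "pyrl_policy": "plastic_only", "pyrl_baseline": "plastic_only",
            "rhebb": "exclude_output_and_constant"}[family]


def build_mask(arch: Architecture, policy: str) -> AnalysisMask:
    """Analysis population for a family.

    * ``all``: every recurrent unit, both axes.
    * ``E_E_only``: excitatory-to-excitatory connections (requires Dale
      signs).
    * ``exclude_output_and_constant``: drop the designated output unit and
      the constant-input units from both axes (rHebb).
    * ``plastic_only``: all units, but only plasticity-mask-true elements.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown analysis policy {policy!r}")
    all_units = np.arange(arch.n_rec)
    if policy == "all":
        return AnalysisMask(all_units, all_units, "all")
    if policy == "E_E_only":
        if arch.dale_signs is None:
            raise ValueError("E_E_only requires a Dale-constrained architecture")
        exc = np.flatnonzero(arch.dale_signs > 0)
        return AnalysisMask(exc, exc, "E_E_only")
    if policy == "exclude_output_and_constant":
        if arch.family != "rhebb":
            raise ValueError("output/constant exclusion applies to the rHebb family")
        drop = {arch.output_unit_index, *arch.constant_input_units}
        keep = np.array([i for i in all_units if i not in drop])
        return AnalysisMask(keep, keep, "exclude_output_and_constant")
    # plastic_only
    if arch.plasticity_mask is None:
        raise ValueError("plastic_only requires a plasticity mask")
    em = arch.plasticity_mask.astype(bool)
    # post units without any analyzed presynapse have no defined post-mean
    posts = all_units[em.sum(axis=1) > 0]
    return AnalysisMask(posts, all_units, "plastic_only", element_mask=em)


def weight_diff(W_last: np.ndarray, W_init: np.ndarray) -> np.ndarray:
    """Signed weight change W^last - W^init."""
    if W_last.shape != W_init.shape:
        raise ValueError("weight matrices must share a shape")
    return W_last - W_init


def post_mean(M: np.ndarray, mask: AnalysisMask) -> np.ndarray:
    """Per-postsynaptic-unit mean of absolute analyzed entries.

    For element-masked populations (pyrl) the divisor is the number of
    analyzed presynapses of each post unit, i.e. the mean over the
    analyzed population rather than over all recurrent units.
    """
    sub = np.abs(mask.submatrix(M))
    em = mask.sub_element_mask()
    if em is None:
        return sub.mean(axis=1)
    counts = em.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("a post unit has no analyzed presynapses")
    return (sub * em).sum(axis=1) / counts


def rank_units(post_mean_vector: np.ndarray) -> np.ndarray:
    """Indices sorted by descending post-mean; ties keep original order."""
    v = np.asarray(post_mean_vector, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("post-mean vector must be finite")
    return np.argsort(-v, kind="stable")


def dist_stats(sample: np.ndarray) -> DistributionStats:
    """Shapiro-Wilk normality plus skewness / excess-kurtosis Z-tests."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("at least 8 observations required")
    if np.ptp(x) == 0:
        raise ValueError("distribution statistics undefined for a constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-n Shapiro p is approximate
        sw = stats.shapiro(x)
        sk = stats.skewtest(x)
        ku = stats.kurtosistest(x)
    return DistributionStats(
        n=int(x.size),
        normality_W=float(sw.statistic), normality_p=float(sw.pvalue),
        skewness=float(stats.skew(x)),
        skew_z=float(sk.statistic), skew_p=float(sk.pvalue),
        kurtosis_excess=float(stats.kurtosis(x)),
        kurt_z=float(ku.statistic), kurt_p=float(ku.pvalue),
    )


def summarize_model(record: TrainingRecord, arch: Architecture,
                    policy: str | None = None) -> WeightChangeSummary:
    """Full weight-change summary of one trained model.

    Applies the analysis mask, forms W^diff, computes post-mean vectors of
    the final weights and of the changes, ranks units by post-mean change,
    and tests all three distributions (two post-mean level, one element
    level on the flattened analyzed changes).
    """
    if policy is None:
        policy = default_policy(record.family)
    mask = build_mask(arch, policy)
    wd = weight_diff(record.W_last.W_rec, record.W_init.W_rec)
    pm_last = post_mean(record.W_last.W_rec, mask)
    pm_diff = post_mean(wd, mask)
    return WeightChangeSummary(
        mask=mask,
        W_diff=wd,
        post_mean_last=pm_last,
        post_mean_diff=pm_diff,
        ranking=rank_units(pm_diff),
        postmean_last_stats=dist_stats(pm_last),
        postmean_diff_stats=dist_stats(pm_diff),
        element_diff_stats=dist_stats(mask.elements(wd)),
    )


def summary_table(summary: WeightChangeSummary):
    """Tabulate the three distribution tests as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for level, st in (("post_mean_last", summary.postmean_last_stats),
                      ("post_mean_diff", summary.postmean_diff_stats),
                      ("element_diff", summary.element_diff_stats)):
        rows.append({
            "level": level, "n": st.n,
            "normality_p": st.normality_p, "normality_W": st.normality_W,
            "skew_p": st.skew_p, "skew_z": st.skew_z, "skewness": st.skewness,
            "kurt_p": st.kurt_p, "kurt_z": st.kurt_z,
            "kurtosis_excess": st.kurtosis_excess,
        })
    return pd.DataFrame(rows)
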