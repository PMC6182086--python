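"""Rank-ordered inactivation sweeps, network-size sweeps and their statistics.

Inactivation sweeps clamp growing numbers of recurrent units -- in
descending, ascending, or shuffled order of their post-mean weight change
-- and measure task accuracy, asking whether the high-plasticity units
carry the behavior.  The factorial (sort order x number inactivated x
system replicate) accuracy grid is analyzed with a fixed-effects two-way
ANOVA with interaction, followed by Tukey-HSD pairwise comparisons of the
sort orders at each lesion size.

Size sweeps retrain a family at several network sizes (five seeds each by
default) and compare final accuracy and post-mean-change skewness across
sizes with the Kruskal-Wallis omnibus test and Dunn's post-hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import summarize_model, default_policy
from .networks import Architecture, InactivationSpec, accuracy
from .records import TrainingRecord
from .tasks import TaskConfig, make_batch

__all__ = [
    "InactivationSweepResult",
    "SizeSweepResult",
    "run_inactivation_sweep",
    "two_way_anova",
    "factorial_dfs",
    "posthoc_pairwise",
    "run_size_sweep",
    "kruskal_wallis",
    "dunn_posthoc",
]

SORT_TYPES = ("descending", "ascending", "shuffled")


@dataclass
class InactivationSweepResult:
    sort_types: tuple
    n_inact_grid: np.ndarray
    accuracies: np.ndarray  # (sort_type, n_inact, system)

    @property
    def n_systems(self) -> int:
        return self.accuracies.shape[2]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, st in enumerate(self.sort_types):
            for j, n in enumerate(self.n_inact_grid):
                for s in range(self.n_systems):
                    rows.append({"sort_type": st, "n_inact": int(n),
                                 "system": s,
                                 "accuracy": self.accuracies[i, j, s]})
        return pd.DataFrame(rows)


@dataclass
class SizeSweepResult:
    family: str
    sizes: np.ndarray
    accuracies: np.ndarray  # (size, seed)
    skewness: np.ndarray  # (size, seed) post-mean-diff skewness
    kw_accuracy: tuple  # (H, p)
    kw_skewness: tuple
    dunn_accuracy: pd.DataFrame
    dunn_skewness: pd.DataFrame


def _clamp_mode(family: str) -> str:
    return "bias_constant" if family == "hf" else "zero_output"


def run_inactivation_sweep(records, archs, task_cfg: TaskConfig,
                           grid=None, rng: np.random.Generator | None = None,
                           n_eval_trials: int = 200,
                           sort_types=SORT_TYPES) -> InactivationSweepResult:
    """Lesion sweep over (sort order x lesion size x system replicate).

    ``records`` and ``archs`` are parallel lists of trained systems of one
    family.  For each system, units are ranked by post-mean weight change
    (descending = most plastic first); for each order and each grid value
    n, the first n units of the order are clamped (zero output, or pinned
    at b_x for the HF family) and accuracy is measured on a fresh
    evaluation batch.  Rankings index the analysis population, so for
    pycog only excitatory units are lesioned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    family = records[0].family
    sums = [summarize_model(rec, arch, default_policy(family))
            for rec, arch in zip(records, archs)]
    pop = sums[0].mask.included_post_units
    if grid is None:
        grid = np.arange(0, len(pop) + 1, 10)
    grid = np.asarray(grid, dtype=int)
    if grid.max() > len(pop):
        raise ValueError("lesion count exceeds the analyzed population")

    acc = np.empty((len(sort_types), len(grid), len(records)))
    for s, (rec, arch, summ) in enumerate(zip(records, archs, sums)):
        units_by_rank = summ.mask.included_post_units[summ.ranking]
        orders = {}
        for st in sort_types:
            if st == "descending":
                orders[st] = units_by_rank
            elif st == "ascending":
                orders[st] = units_by_rank[::-1]
            elif st == "shuffled":
                orders[st] = rng.permutation(units_by_rank)
            else:
                raise ValueError(f"unknown sort type {st!r}")
        for j, n in enumerate(grid):
            # one evaluation batch per (system, lesion size), shared across
            # sort orders: order comparisons are paired, and the n = 0 cell
            # is exactly the unlesioned baseline for every order
            batch_seed = int(rng.integers(2 ** 31))
            sim_seed = int(rng.integers(2 ** 31))
            batch = make_batch(task_cfg, n_eval_trials, "alternating",
                               np.random.default_rng(batch_seed))
            for i, st in enumerate(sort_types):
                spec = (InactivationSpec(tuple(int(u) for u in orders[st][:n]),
                                         _clamp_mode(family))
                        if n > 0 else None)
                acc[i, j, s] = accuracy(rec.W_last, arch, batch,
                                        inactivation=spec,
                                        rng=np.random.default_rng(sim_seed))
    return InactivationSweepResult(tuple(sort_types), grid, acc)


def factorial_dfs(n_levels: int, n_orders: int, n_systems: int):
    """Degrees of freedom of the full-factorial two-way fixed-effects design."""
    df_a = n_levels - 1
    df_b = n_orders - 1
    df_ab = df_a * df_b
    df_err = n_levels * n_orders * (n_systems - 1)
    return {"n_inact": df_a, "sort_type": df_b, "interaction": df_ab,
            "error": df_err}


def two_way_anova(result: InactivationSweepResult) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction on the accuracy grid.

    Factors: number inactivated (categorical) and sort order; system
    replicates supply the error term.  Returns a table with rows
    n_inact, sort_type, interaction, each with (df_factor, df_error, F, p).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if result.n_systems < 2:
        raise ValueError("need >= 2 replicates per cell")
    df = result.to_frame()
    model = ols("accuracy ~ C(n_inact) * C(sort_type)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_err = int(table.loc["Residual", "df"])
    rows = []
    for label, name in (("C(n_inact)", "n_inact"),
                        ("C(sort_type)", "sort_type"),
                        ("C(n_inact):C(sort_type)", "interaction")):
        rows.append({"factor": name,
                     "df_factor": int(table.loc[label, "df"]),
                     "df_error": df_err,
                     "F": float(table.loc[label, "F"]),
                     "p": float(table.loc[label, "PR(>F)"])})
    return pd.DataFrame(rows)


def posthoc_pairwise(result: InactivationSweepResult,
                     method: str = "tukey_hsd") -> pd.DataFrame:
    """Tukey-HSD comparisons of sort orders at each lesion size."""
    if method != "tukey_hsd":
        raise ValueError("only tukey_hsd is supported")
    if len(result.sort_types) < 2:
        raise ValueError("need >= 2 sort types")
    rows = []
    for j, n in enumerate(result.n_inact_grid):
        groups = [result.accuracies[i, j, :] for i in range(len(result.sort_types))]
        res = stats.tukey_hsd(*groups)
        for a, b in combinations(range(len(groups)), 2):
            rows.append({
                "n_inact": int(n),
                "pair": f"{result.sort_types[a]}-{result.sort_types[b]}",
                "mean_diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                "p_adj": float(res.pvalue[a, b]),
            })
    return pd.DataFrame(rows)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p over a list of sample groups."""
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups, labels=None, p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) ),
    with T the tie correction sum(t^3 - t) / (12 (N - 1)); two-sided
    normal p-values, Holm-adjusted by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start:start + g.size])))
        sizes.append(g.size)
        start += g.size
    var0 = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(range(len(groups)), 2):
        se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"pair": f"{labels[a]}-{labels[b]}", "z": float(z),
                     "p": float(p)})
    df = pd.DataFrame(rows)
    if p_adjust == "holm":
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_adj"] = adj
    elif p_adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {p_adjust!r}")
    return df


def run_size_sweep(train_fn, family: str, sizes, task_cfg: TaskConfig,
                   n_seeds: int = 5, analysis_policy: str | None = None,
                   root_seed: int = 0) -> SizeSweepResult:
    """Train a fresh model per (size, seed); compare across sizes.

    ``train_fn(family, n_rec, seed)`` must return a (TrainingRecord,
    Architecture) pair -- typically presets.train_family.  Failed training
    runs are recorded as NaN cells.  Accuracy and post-mean-change
    skewness are compared across sizes with Kruskal-Wallis and Dunn's
    test.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size < 2:
        raise ValueError("need at least two sizes")
    acc = np.full((sizes.size, n_seeds), np.nan)
    skw = np.full((sizes.size, n_seeds), np.nan)
    for i, size in enumerate(sizes):
        for s in range(n_seeds):
            seed = root_seed + 1000 * i + s
            try:
                rec, arch = train_fn(family, int(size), seed)
            except (FloatingPointError, ValueError):
                continue  # failed cell stays missing
            rng = np.random.default_rng(seed + 7)
            batch = make_batch(task_cfg, 500, "alternating", rng)
            acc[i, s] = accuracy(rec.W_last, arch, batch, rng=rng)
            summ = summarize_model(rec, arch,
                                   analysis_policy or default_policy(rec.family))
            skw[i, s] = summ.postmean_diff_stats.skewness
    labels = [str(s) for s in sizes]
    acc_groups = [a[np.isfinite(a)] for a in acc]
    skw_groups = [a[np.isfinite(a)] for a in skw]
    return SizeSweepResult(
        family=family, sizes=sizes, accuracies=acc, skewness=skw,
        kw_accuracy=kruskal_wallis(acc_groups),
        kw_skewness=kruskal_wallis(skw_groups),
        dunn_accuracy=dunn_posthoc(acc_groups, labels),
        dunn_skewness=dunn_posthoc(skw_groups, labels),
    )
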