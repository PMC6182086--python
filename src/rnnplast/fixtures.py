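"""Synthetic weight-change fixtures with planted structure.

These generators emulate the statistical signature the analysis pipeline
is designed to detect -- weight changes concentrated on a few
postsynaptic rows -- without any training, so every downstream stage can
be tested quickly and deterministically.  Planted rows draw their changes
from a wider Gaussian than the background rows; only the weight structure
is emulated, not temporal activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import NetworkParameters
from .records import TrainingRecord

__all__ = ["PlantedPlasticityFixture", "make_planted_fixture", "make_toy_record"]


@dataclass
class PlantedPlasticityFixture:
    n_units: int
    k_hot: int
    sigma_background: float
    sigma_hot: float
    seed: int
    W_init: np.ndarray
    W_last: np.ndarray
    true_hot_indices: np.ndarray

    @property
    def record(self) -> TrainingRecord:
        """View the fixture as a synthetic training record (family 'hf')."""
        mk = lambda W: NetworkParameters(W_rec=W.copy(),
                                         W_in=np.zeros((self.n_units, 4)),
                                         b_x=np.zeros(self.n_units),
                                         W_out=np.zeros((1, self.n_units)),
                                         b_out=np.zeros(1))
        return TrainingRecord(family="hf", W_init=mk(self.W_init),
                              W_last=mk(self.W_last),
                              performance_trace=np.zeros((0, 2)),
                              seed=self.seed,
                              config={"synthetic": "planted_plasticity"})


def make_planted_fixture(n: int, k: int, sigma_bg: float, sigma_hot: float,
                         seed: int, init_sigma: float = 0.1,
                         ) -> PlantedPlasticityFixture:
    """Gaussian initial weights plus row-localized changes.

    ``k`` postsynaptic rows ("hot" units) receive changes with standard
    deviation ``sigma_hot``; the remaining rows get ``sigma_bg``.  ``k = 0``
    is allowed as a null control (no planted structure).
    """
    if not (0 <= k < n):
        raise ValueError("require 0 <= k < n")
    if k > 0 and not (sigma_hot > sigma_bg > 0):
        raise ValueError("require sigma_hot > sigma_bg > 0")
    if sigma_bg <= 0:
        raise ValueError("sigma_bg must be positive")
    rng = np.random.default_rng(seed)
    W_init = rng.normal(0.0, init_sigma, (n, n))
    W_diff = rng.normal(0.0, sigma_bg, (n, n))
    hot = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    if k:
        W_diff[hot, :] = rng.normal(0.0, sigma_hot, (k, n))
    return PlantedPlasticityFixture(
        n_units=n, k_hot=k, sigma_background=sigma_bg, sigma_hot=sigma_hot,
        seed=seed, W_init=W_init, W_last=W_init + W_diff,
        true_hot_indices=np.sort(hot))


def make_toy_record(n: int = 3, seed: int = 0) -> TrainingRecord:
    """Tiny record with hand-checkable weights (exact rational post-means).

    W_init = 0 and W_last = [[1,-1,0],[0,0,0],[2,2,2]] padded to ``n``,
    so post-mean changes start (2/3, 0, 2, 0, ...).
    """
    if n > 5:
        raise ValueError("toy records are capped at 5 units")
    base = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
    W_last = np.zeros((n, n))
    m = min(n, 3)
    W_last[:m, :m] = base[:m, :m]
    mk = lambda W: NetworkParameters(W_rec=W.copy(), W_in=np.zeros((n, 4)),
                                     b_x=np.zeros(n),
                                     W_out=np.zeros((1, n)), b_out=np.zeros(1))
    return TrainingRecord(family="hf", W_init=mk(np.zeros((n, n))),
                          W_last=mk(W_last), performance_trace=np.zeros((0, 2)),
                          seed=seed, config={"synthetic": "toy"})
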