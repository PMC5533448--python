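"""Synthetic imbalanced two-class datasets and stub objectives for testing.

``make_imbalanced`` draws two spherical Gaussian clusters with a controllable
distance between the class means, emulating the shape of bioassay/clinical
screening tables: a few dozen positives against hundreds to tens of
thousands of negatives, ratios from ~2:1 to ~1000:1.  The method under test
is feature-agnostic, so Gaussian blobs exercise it fully; a Student-t option
provides heavy tails for robustness checks.

``make_grid_objective`` turns an explicit (S, K) -> (kappa, accuracy) table
into a deterministic, call-counted fitness function — the stand-in for the
expensive cross-validated classifier in optimizer tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import LabeledDataset
from .swarm_balancer import FitnessRecord

__all__ = ["SynthSpec", "make_imbalanced", "make_grid_objective", "GridObjective"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one imbalanced dataset.

    ``separation`` is the distance between class means along the first axis,
    in units of the per-class standard deviation (``noise_sd``).
    """

    n_majority: int
    n_minority: int
    n_features: int = 10
    separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    tails: str = "gaussian"

    def __post_init__(self):
        if self.n_minority < 2:
            raise ValueError("n_minority must be >= 2")
        if self.n_majority < self.n_minority:
            raise ValueError("n_majority must be >= n_minority")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tails not in ("gaussian", "student"):
            raise ValueError("tails must be 'gaussian' or 'student'")


def make_imbalanced(spec: SynthSpec) -> LabeledDataset:
    """Two-cluster dataset with exact class counts; deterministic given seed.

    Majority rows (label 0) come first, then minority rows (label 1), so the
    row stream the windowed balancer sees has the class layout of a sorted
    export; pass ``shuffle=True`` to the balancer for i.i.d. order.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_majority + spec.n_minority
    if spec.tails == "gaussian":
        X = rng.normal(size=(n, spec.n_features))
    else:
        X = rng.standard_t(df=3, size=(n, spec.n_features))
    X *= spec.noise_sd
    # minority mean sits `separation` pooled-sd units away along axis 0
    X[spec.n_majority:, 0] += spec.separation * spec.noise_sd
    labels = np.concatenate(
        [np.zeros(spec.n_majority, dtype=int), np.ones(spec.n_minority, dtype=int)]
    )
    return LabeledDataset(X, labels)


class GridObjective:
    """Deterministic (S, K) -> FitnessRecord lookup with nearest-key fallback
    and a call counter; the instrumented stand-in for CV fitness."""

    def __init__(self, table: dict[tuple[int, int], tuple[float, float]]):
        if not table:
            raise ValueError("table must be nonempty")
        self.table = {k: FitnessRecord(kappa=v[0], accuracy=v[1])
                      for k, v in table.items()}
        self.calls = 0
        self.history: list[tuple[int, int]] = []

    def __call__(self, S: int, K: int) -> FitnessRecord:
        self.calls += 1
        self.history.append((S, K))
        hit = self.table.get((S, K))
        if hit is None:
            # nearest key by Euclidean distance, ties toward the smaller key
            key = min(
                sorted(self.table),
                key=lambda k: (k[0] - S) ** 2 + (k[1] - K) ** 2,
            )
            hit = self.table[key]
        return hit


def make_grid_objective(
    table: dict[tuple[int, int], tuple[float, float]]
) -> GridObjective:
    """Wrap an explicit {(S, K): (kappa, accuracy)} map as an objective."""
    return GridObjective(table)
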