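"""SMOTE parameterized by oversampling percentage S and neighbor count K.

A synthetic minority sample is a random point on the segment between a
minority seed x_i and one of its K nearest minority neighbors x_t:

    x_new = x_i + u * (x_t - x_i),   u ~ Uniform[0, 1]

S is an integer percentage: S = 100 synthesizes one new sample per existing
minority sample, doubling the minority class.  The total synthetic count is
floor(M * S / 100) for M minority rows, the sizing convention recovered from
published (S, M, minority-total) triples; the quota is distributed round-robin
over minority rows in row order, which generalizes "each sample synthesizes
S/100 copies" to S values that are not multiples of 100 while staying
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import DegenerateInputError, LabeledDataset

__all__ = [
    "BalancerParams",
    "minority_neighbors",
    "synthesis_count",
    "smote_augment",
    "param_bounds",
]


@dataclass(frozen=True)
class BalancerParams:
    """The (S, K) pair SMOTE consumes and the swarms search over."""

    S_percent: int
    K_neighbors: int

    def __post_init__(self) -> None:
        if self.S_percent < 0:
            raise ValueError("S_percent must be non-negative")
        if self.K_neighbors < 1:
            raise ValueError("K_neighbors must be >= 1")


def minority_neighbors(minority_features: np.ndarray, index: int, K: int) -> np.ndarray:
    """Indices of the K minority rows nearest (Euclidean) to ``index``.

    The seed row itself is excluded; distance ties break toward the lower
    row id.  K is clamped to M - 1 when it exceeds the available peers.
    """
    X = np.asarray(minority_features, dtype=float)
    M = X.shape[0]
    if M < 2:
        raise DegenerateInputError("need at least 2 minority rows to find neighbors")
    K = min(K, M - 1)
    d = np.linalg.norm(X - X[index], axis=1)
    d[index] = np.inf
    # stable sort on distance → ties resolved by lower row id
    order = np.argsort(d, kind="stable")
    return order[:K]


def synthesis_count(M: int, S_percent: int) -> int:
    """Number of synthetic samples for M minority rows at percentage S."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if S_percent < 0:
        raise ValueError("S_percent must be >= 0")
    return (M * S_percent) // 100


def smote_augment(
    ds: LabeledDataset,
    params: BalancerParams,
    rng: np.random.Generator | int | None = None,
    scale: bool = False,
) -> LabeledDataset:
    """Append synthetic minority rows to ``ds`` per the (S, K) parameters.

    All original rows are preserved unchanged and come first, in order;
    synthetic rows (label 1) follow.  Deterministic for a seeded ``rng``.
    ``scale`` switches the neighbor metric to z-scored features; synthesis
    still happens in the raw feature space.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    minority_mask = ds.labels == 1
    M = int(minority_mask.sum())
    if M < 2:
        raise DegenerateInputError(
            f"cannot synthesize from {M} minority row(s); need at least 2"
        )
    n_syn = synthesis_count(M, params.S_percent)
    if n_syn == 0:
        return LabeledDataset(
            ds.features.copy(), ds.labels.copy(), list(ds.feature_names)
        )

    minority = ds.features[minority_mask]
    K = params.K_neighbors
    if K > M - 1:
        warnings.warn(
            f"K={K} exceeds available minority peers ({M - 1}); clamping",
            stacklevel=2,
        )
        K = M - 1

    metric_space = minority
    if scale:
        sd = minority.std(axis=0)
        sd[sd == 0] = 1.0
        metric_space = (minority - minority.mean(axis=0)) / sd
    neighbor_ids = [minority_neighbors(metric_space, i, K) for i in range(M)]

    # round-robin quota: base floor(n_syn/M) each, first n_syn % M rows get +1
    base, extra = divmod(n_syn, M)
    quotas = np.full(M, base, dtype=int)
    quotas[:extra] += 1

    synthetic = np.empty((n_syn, ds.n_features))
    pos = 0
    for i in range(M):
        for _ in range(quotas[i]):
            t = neighbor_ids[i][rng.integers(len(neighbor_ids[i]))]
            u = rng.uniform()
            synthetic[pos] = minority[i] + u * (minority[t] - minority[i])
            pos += 1

    features = np.vstack([ds.features, synthetic])
    labels = np.concatenate([ds.labels, np.ones(n_syn, dtype=int)])
    return LabeledDataset(features, labels, list(ds.feature_names))


def param_bounds(
    ds: LabeledDataset, mode: str = "experiment1"
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Integer search ranges ((S_min, S_max), (K_min, K_max)) for a dataset.

    ``experiment1``: S from 10% up to 100·(majority/minority); K from 2 to M.
    ``experiment2``: same upper bounds but S starts at 100 (the windowed
    search's initialization convention).  The K upper bound is additionally
    clamped to M - 1 at use time by the synthesizer.
    """
    c = ds.class_counts()
    if c.positive == 0 or c.negative == 0:
        raise DegenerateInputError("param bounds undefined with an empty class")
    M = min(c.positive, c.negative)
    n_maj = max(c.positive, c.negative)
    s_upper = (100 * n_maj) // M
    if mode == "experiment1":
        s_lower = 10
    elif mode == "experiment2":
        s_lower = 100
    else:
        raise ValueError(f"unknown mode {mode!r}")
    s_upper = max(s_upper, s_lower)
    return (s_lower, s_upper), (2, max(M, 2))
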