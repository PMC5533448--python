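"""Pluggable classifier and the SMOTE-then-k-fold-CV fitness evaluation.

The default learner is a small feed-forward network: one hidden layer of
logistic units trained by plain gradient descent.  It is deliberately weak —
the point of the surrounding search is that rebalancing, not classifier
tuning, moves kappa out of the non-credible band.

``evaluate_with_params`` reproduces the published protocol: SMOTE is applied
to the FULL dataset first, then k-fold cross validation runs on the augmented
dataset and the per-fold confusion counts are pooled.  Synthetic rows derived
from a test-fold original therefore leak information into training folds;
``leak_free=True`` instead re-synthesizes inside each training fold (flagged
as a deviation from the published protocol).
"""

from __future__ import annotations

import time
import json
from dataclasses import dataclass, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
import warnings

from .core_data import LabeledDataset, kfold_splits
from .metrics import EvalResult, eval_result
from .smote import BalancerParams, smote_augment

__all__ = ["ClassifierSpec", "fit_predict", "evaluate_with_params", "FitnessCache"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the verification classifier.

    hidden_units/epochs/learning_rate parameterize a single-hidden-layer
    logistic network trained with constant-rate gradient descent.
    """

    kind: str = "mlp"
    hidden_units: int = 10
    epochs: int = 200
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _build(spec: ClassifierSpec) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation="logistic",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        momentum=0.0,
        nesterovs_momentum=False,
        early_stopping=False,
        random_state=spec.seed,
        alpha=0.0,
    )


def fit_predict(
    spec: ClassifierSpec,
    train: LabeledDataset,
    test: LabeledDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on ``train``, return (hard labels, positive-class scores) on ``test``.

    Deterministic given ``spec.seed``; scores lie in [0, 1] and labels are the
    scores thresholded at 0.5.
    """
    if spec.kind != "mlp":
        raise ValueError(f"unknown classifier kind {spec.kind!r}")
    if len(np.unique(train.labels)) < 2:
        raise ValueError(
            "training set holds a single class; rebalance before fitting"
        )
    clf = _build(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(train.features, train.labels)
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    scores = clf.predict_proba(test.features)[:, pos_col]
    return (scores >= 0.5).astype(int), scores


class FitnessCache:
    """Memoizes evaluate_with_params on (S, K) so a swarm revisiting a grid
    point never retrains; also keeps a JSON-lines trace of evaluations."""

    def __init__(self, trace_path=None):
        self._store: dict[tuple[int, int], tuple[EvalResult, int, int]] = {}
        self.trace_path = trace_path
        self.calls = 0
        self.misses = 0

    def get(self, key):
        return self._store.get(key)

    def put(self, key, value):
        self._store[key] = value

    def log(self, S, K, res: EvalResult, psize, nsize, elapsed):
        if self.trace_path is None:
            return
        row = {"S": S, "K": K, "accuracy": res.accuracy, "kappa": res.kappa,
               "Psize": psize, "Nsize": nsize, "elapsed": elapsed}
        with open(self.trace_path, "a") as fh:
            fh.write(json.dumps(row) + "\n")


def evaluate_with_params(
    ds: LabeledDataset,
    params: BalancerParams,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    leak_free: bool = False,
    cache: FitnessCache | None = None,
) -> tuple[EvalResult, int, int]:
    """SMOTE at (S, K), then k-fold CV; returns (EvalResult, Psize, Nsize).

    Psize is the post-augmentation minority count, Nsize the majority count.
    Confusion counts are pooled across folds into a single metric block.
    Fully determined by ``seed`` (which drives synthesis and fold assignment)
    and ``spec.seed`` (which drives weight initialization).
    """
    spec = spec or ClassifierSpec()
    key = (params.S_percent, params.K_neighbors)
    if cache is not None:
        cache.calls += 1
        hit = cache.get(key)
        if hit is not None:
            return hit

    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    if leak_free:
        result = _leak_free_eval(ds, params, spec, folds, seed, rng)
        aug_minority = ds.class_counts().positive  # training-fold-local synthesis
    else:
        aug = smote_augment(ds, params, rng)
        result = _pooled_cv(aug, spec, folds, seed)
        aug_minority = aug.class_counts().positive
    nsize = ds.class_counts().negative
    out = (result, aug_minority, nsize)
    if cache is not None:
        cache.misses += 1
        cache.put(key, out)
        cache.log(*key, result, aug_minority, nsize, time.perf_counter() - t0)
    return out


def _pooled_cv(ds: LabeledDataset, spec: ClassifierSpec, folds: int,
               seed: int) -> EvalResult:
    all_true, all_scores = [], []
    for i, (tr, te) in enumerate(kfold_splits(ds, folds, stratified=True, seed=seed)):
        train, test = ds.subset(tr), ds.subset(te)
        _, scores = fit_predict(replace(spec, seed=spec.seed + i), train, test)
        all_true.append(test.labels)
        all_scores.append(scores)
    true = np.concatenate(all_true)
    scores = np.concatenate(all_scores)
    pred = (scores >= 0.5).astype(int)
    return eval_result(true, pred, scores)


def _leak_free_eval(ds, params, spec, folds, seed, rng) -> EvalResult:
    all_true, all_scores = [], []
    for i, (tr, te) in enumerate(kfold_splits(ds, folds, stratified=True, seed=seed)):
        train = smote_augment(ds.subset(tr), params, rng)
        test = ds.subset(te)
        _, scores = fit_predict(replace(spec, seed=spec.seed + i), train, test)
        all_true.append(test.labels)
        all_scores.append(scores)
    true = np.concatenate(all_true)
    scores = np.concatenate(all_scores)
    return eval_result(true, (scores >= 0.5).astype(int), scores)
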