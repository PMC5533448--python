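"""The swarm balancing algorithm: kappa-floor-constrained (S, K) search.

The search does not maximize accuracy unconditionally: accuracy only counts
once the result is *credible*.  A candidate replaces the incumbent iff

    [ min(best.kappa, current.kappa) > T  and  current.accuracy > best.accuracy ]
    or
    [ current.kappa > T  and  best.kappa < T ]

with T the kappa floor (default 0.4, the lower edge of the moderate
credibility band).  The second branch lets a first credible solution displace
a high-accuracy-but-non-credible incumbent regardless of accuracy — the
majority-vote trap this whole method exists to escape.  An incumbent with
kappa exactly T matches neither branch and is kept; faithful to the rule as
stated.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .classifier_eval import ClassifierSpec, FitnessCache, evaluate_with_params
from .core_data import LabeledDataset
from .metrics import EvalResult, credibility_band
from .optimizers import SwarmConfig, TraceEntry, optimize
from .smote import BalancerParams, param_bounds

__all__ = ["FitnessRecord", "BalanceReport", "accept_candidate", "swarm_balance"]


@dataclass(frozen=True)
class FitnessRecord:
    """The two objectives a visited (S, K) point is judged by."""

    kappa: float
    accuracy: float


@dataclass
class BalanceReport:
    best_params: BalancerParams
    result: EvalResult
    psize: int
    nsize: int
    credible: bool
    band: str
    trace: list[TraceEntry] = field(repr=False)
    elapsed_s: float = 0.0
    evaluations: int = 0
    unique_evaluations: int = 0


def accept_candidate(best: FitnessRecord, current: FitnessRecord,
                     T: float = 0.4) -> bool:
    """True iff ``current`` should replace ``best`` under the kappa floor T."""
    if not -1.0 < T < 1.0:
        raise ValueError(f"kappa floor must lie in (-1, 1), got {T}")
    if min(best.kappa, current.kappa) > T and current.accuracy > best.accuracy:
        return True
    if current.kappa > T and best.kappa < T:
        return True
    return False


def swarm_balance(
    ds: LabeledDataset,
    algorithm: str = "pso",
    cfg: SwarmConfig | None = None,
    spec: ClassifierSpec | None = None,
    bounds=None,
    warm_start: BalancerParams | None = None,
    T: float = 0.4,
    folds: int = 10,
    seed: int = 0,
    bounds_mode: str = "experiment1",
    trace_path=None,
    objective=None,
) -> BalanceReport:
    """Search (S, K) with a swarm, judging each point by SMOTE + k-fold CV.

    Fitness evaluations are cached on (S, K): a swarm revisiting a grid point
    reuses the stored record rather than retraining.  When no visited point
    clears the kappa floor the max-kappa point is returned flagged
    ``credible=False`` rather than failing.

    ``objective`` may override the CV fitness with any callable
    ``(S, K) -> FitnessRecord`` (used with deterministic stub objectives in
    tests); the report's ``result`` then holds the FitnessRecord itself and
    psize/nsize are the dataset's raw class counts.
    """
    cfg = cfg or SwarmConfig(seed=seed)
    spec = spec or ClassifierSpec(seed=seed)
    if bounds is None:
        bounds = param_bounds(ds, mode=bounds_mode)
    cache = FitnessCache(trace_path=trace_path)

    if objective is None:

        def objective(S: int, K: int) -> FitnessRecord:
            res, _, _ = evaluate_with_params(
                ds, BalancerParams(S, K), spec, folds=folds, seed=seed,
                cache=cache,
            )
            return FitnessRecord(kappa=res.kappa, accuracy=res.accuracy)

    else:
        inner = objective
        counts = ds.class_counts()

        def objective(S: int, K: int) -> FitnessRecord:
            cache.calls += 1
            hit = cache.get((S, K))
            if hit is None:
                cache.misses += 1
                fit = inner(S, K)
                hit = (fit, counts.positive, counts.negative)
                cache.put((S, K), hit)
            return hit[0]

    comparator = lambda best, cur: accept_candidate(best, cur, T)

    t0 = time.perf_counter()
    ws = (warm_start.S_percent, warm_start.K_neighbors) if warm_start else None
    best_point, best_fit, trace = optimize(
        objective, bounds, algorithm, cfg, comparator, warm_start=ws
    )
    elapsed = time.perf_counter() - t0

    credible = best_fit.kappa > T
    if not credible:
        # no visited point cleared the floor: report the max-kappa point
        best_entry = max(trace, key=lambda e: e.fitness.kappa)
        best_point = (best_entry.S, best_entry.K)
        best_fit = best_entry.fitness

    params = BalancerParams(*best_point)
    cached = cache.get(best_point)
    assert cached is not None, "returned point was never evaluated"
    result, psize, nsize = cached
    return BalanceReport(
        best_params=params,
        result=result,
        psize=psize,
        nsize=nsize,
        credible=credible,
        band=credibility_band(best_fit.kappa),
        trace=trace,
        elapsed_s=elapsed,
        evaluations=cache.calls,
        unique_evaluations=cache.misses,
    )
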