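"""Adaptive swarm balancing: windowed search with parameter propagation.

Large imbalanced datasets are treated as a stream cut into N disjoint windows
whose lengths grow in 1:2:...:N proportion (N = 3 by default).  Each class is
segmented independently so every window preserves the stream's class mix.
Window 1 runs a fresh swarm search; windows 2..N-1 run searches warm-started
at the previous window's best (S, K); the final window runs NO search — it is
evaluated once under window N-1's parameters.  The headline result is the
arithmetic mean of the per-window best accuracies and kappas.

The window-length rule: with W = N(N+1)/2, window x gets a base length of
x * floor(count / W); the remainder is distributed one row at a time cycling
from the last window toward the first (w_N, w_{N-1}, ..., w_1, w_N, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier_eval import ClassifierSpec, evaluate_with_params
from .core_data import LabeledDataset
from .metrics import EvalResult, credibility_band
from .optimizers import SwarmConfig
from .smote import BalancerParams
from .swarm_balancer import BalanceReport, swarm_balance

__all__ = [
    "WindowPlan",
    "WindowRecord",
    "AdaptiveReport",
    "plan_windows",
    "split_windows",
    "adaptive_balance",
]


@dataclass(frozen=True)
class WindowPlan:
    """Per-class segment lengths for the N-window progressive partition."""

    n_windows: int
    positive_lengths: tuple[int, ...]
    negative_lengths: tuple[int, ...]

    def window_sizes(self) -> tuple[int, ...]:
        return tuple(
            p + n for p, n in zip(self.positive_lengths, self.negative_lengths)
        )


@dataclass
class WindowRecord:
    window: int
    params: BalancerParams | None
    accuracy: float
    kappa: float
    psize: int
    nsize: int
    searched: bool
    result: EvalResult | None = None
    report: BalanceReport | None = field(default=None, repr=False)
    excluded: bool = False


@dataclass
class AdaptiveReport:
    final_accuracy: float
    final_kappa: float
    band: str
    windows: list[WindowRecord]
    audit: list[WindowRecord] = field(default_factory=list)
    searches_run: int = 0


def plan_windows(class_count: int, n_windows: int = 3) -> list[int]:
    """Segment lengths for one class; sums exactly to ``class_count``."""
    if class_count < 1:
        raise ValueError("class_count must be >= 1")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    W = n_windows * (n_windows + 1) // 2
    base = class_count // W
    lengths = [x * base for x in range(1, n_windows + 1)]
    remainder = class_count - sum(lengths)
    w = n_windows - 1
    while remainder > 0:
        lengths[w] += 1
        remainder -= 1
        w = w - 1 if w > 0 else n_windows - 1
    return lengths


def make_window_plan(ds: LabeledDataset, n_windows: int = 3) -> WindowPlan:
    c = ds.class_counts()
    return WindowPlan(
        n_windows=n_windows,
        positive_lengths=tuple(plan_windows(c.positive, n_windows)),
        negative_lengths=tuple(plan_windows(c.negative, n_windows)),
    )


def split_windows(ds: LabeledDataset, plan: WindowPlan) -> list[LabeledDataset]:
    """Cut each class's rows sequentially per the plan and re-join per window.

    Windows are disjoint and jointly exhaustive; within each window, rows keep
    their original relative order.
    """
    c = ds.class_counts()
    if sum(plan.positive_lengths) != c.positive:
        raise ValueError("plan positive lengths do not sum to positive count")
    if sum(plan.negative_lengths) != c.negative:
        raise ValueError("plan negative lengths do not sum to negative count")
    pos_idx = np.flatnonzero(ds.labels == 1)
    neg_idx = np.flatnonzero(ds.labels == 0)
    windows = []
    p0 = n0 = 0
    for pl, nl in zip(plan.positive_lengths, plan.negative_lengths):
        idx = np.sort(np.concatenate([pos_idx[p0:p0 + pl], neg_idx[n0:n0 + nl]]))
        windows.append(ds.subset(idx))
        p0 += pl
        n0 += nl
    return windows


def adaptive_balance(
    ds: LabeledDataset,
    algorithm: str = "pso",
    cfg: SwarmConfig | None = None,
    spec: ClassifierSpec | None = None,
    n_windows: int = 3,
    T: float = 0.4,
    folds: int = 10,
    seed: int = 0,
    shuffle: bool = False,
    audit: bool = False,
    objective_factory=None,
) -> AdaptiveReport:
    """Run the windowed adaptive search and average the per-window results.

    Exactly ``n_windows - 1`` swarm searches run; the last window is evaluated
    once under the previous window's best parameters.  With ``audit=True``
    every window >= 2 is additionally evaluated under each earlier window's
    distinct best parameters (the "processed state" rows); audit rows never
    enter the final averages.  A window with fewer than 2 minority rows cannot
    be synthesized from: it is flagged, excluded from the averages, and search
    falls through to the next window.  ``shuffle`` applies one seeded
    permutation before windowing for i.i.d. rather than stream semantics.
    ``objective_factory(window_ds) -> (S, K) -> FitnessRecord``, when given,
    replaces the CV fitness (deterministic stubs in tests).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    cfg = cfg or SwarmConfig(seed=seed)
    spec = spec or ClassifierSpec(seed=seed)
    if shuffle:
        perm = np.random.default_rng(seed).permutation(ds.n_rows)
        ds = ds.subset(perm)
    if n_windows == 1:
        rep = swarm_balance(
            ds, algorithm, cfg, spec, T=T, folds=folds, seed=seed,
            bounds_mode="experiment2",
            objective=objective_factory(ds) if objective_factory else None,
        )
        rec = WindowRecord(
            window=1, params=rep.best_params, accuracy=rep.result.accuracy,
            kappa=rep.result.kappa, psize=rep.psize, nsize=rep.nsize,
            searched=True, result=rep.result if isinstance(rep.result, EvalResult)
            else None, report=rep,
        )
        return AdaptiveReport(
            final_accuracy=rec.accuracy, final_kappa=rec.kappa,
            band=credibility_band(rec.kappa), windows=[rec], searches_run=1,
        )

    plan = make_window_plan(ds, n_windows)
    windows = split_windows(ds, plan)

    records: list[WindowRecord] = []
    audit_rows: list[WindowRecord] = []
    prev_params: BalancerParams | None = None
    searches = 0

    for x, win in enumerate(windows, start=1):
        mino = win.minority_count()
        if mino < 2 or win.class_counts().positive < 2:
            warnings.warn(
                f"window {x} has {win.class_counts().positive} minority row(s); "
                "cannot synthesize — excluded from averages",
                stacklevel=2,
            )
            records.append(WindowRecord(
                window=x, params=prev_params, accuracy=float("nan"),
                kappa=float("nan"), psize=win.class_counts().positive,
                nsize=win.class_counts().negative, searched=False,
                excluded=True,
            ))
            continue

        if audit and x > 1 and prev_params is not None:
            seen = set()
            for earlier in records:
                p = earlier.params
                if p is None or earlier.excluded or (p.S_percent, p.K_neighbors) in seen:
                    continue
                seen.add((p.S_percent, p.K_neighbors))
                res, psz, nsz = evaluate_with_params(
                    win, p, spec, folds=folds, seed=seed
                )
                audit_rows.append(WindowRecord(
                    window=x, params=p, accuracy=res.accuracy, kappa=res.kappa,
                    psize=psz, nsize=nsz, searched=False, result=res,
                ))

        if x < n_windows:
            rep = swarm_balance(
                win, algorithm, cfg, spec,
                warm_start=prev_params, T=T, folds=folds, seed=seed + x,
                bounds_mode="experiment2",
                objective=objective_factory(win) if objective_factory else None,
            )
            searches += 1
            res = rep.result
            acc = res.accuracy if isinstance(res, EvalResult) else res.accuracy
            kap = res.kappa if isinstance(res, EvalResult) else res.kappa
            records.append(WindowRecord(
                window=x, params=rep.best_params, accuracy=acc, kappa=kap,
                psize=rep.psize, nsize=rep.nsize, searched=True,
                result=res if isinstance(res, EvalResult) else None, report=rep,
            ))
            prev_params = rep.best_params
        else:
            # final window: evaluation only, under window N-1's parameters
            if prev_params is None:
                raise RuntimeError("no earlier window produced parameters")
            if objective_factory is not None:
                fit = objective_factory(win)(
                    prev_params.S_percent, prev_params.K_neighbors
                )
                c = win.class_counts()
                records.append(WindowRecord(
                    window=x, params=prev_params, accuracy=fit.accuracy,
                    kappa=fit.kappa, psize=c.positive, nsize=c.negative,
                    searched=False,
                ))
            else:
                res, psz, nsz = evaluate_with_params(
                    win, prev_params, spec, folds=folds, seed=seed + x
                )
                records.append(WindowRecord(
                    window=x, params=prev_params, accuracy=res.accuracy,
                    kappa=res.kappa, psize=psz, nsize=nsz, searched=False,
                    result=res,
                ))

    included = [r for r in records if not r.excluded]
    if not included:
        raise ValueError("no window could be evaluated")
    final_acc = float(np.mean([r.accuracy for r in included]))
    final_kap = float(np.mean([r.kappa for r in included]))
    return AdaptiveReport(
        final_accuracy=final_acc,
        final_kappa=final_kap,
        band=credibility_band(final_kap),
        windows=records,
        audit=audit_rows,
        searches_run=searches,
    )
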