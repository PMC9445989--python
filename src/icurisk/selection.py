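"""Greedy, importance-ranked risk-function selection over temporal splits.

The full model is too large to inspect function by function, so the model
is reduced: candidates are ranked by their mean importance (mean absolute
log-odds contribution) across the five temporal splits, then for each size
k = 1..cap a model restricted to the top-k candidates is retrained on the
full split's training data and scored by PR-AUC on the full validation
split; the k with the best validation PR-AUC wins (smallest k on ties).
2D candidates are unordered pairs of the selected 1D features, added on
the residuals of the frozen 1D model.

Selection never sees hold-out data: the hold-out indices are simply not an
argument to any operation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import Split, SplitPlan, pr_auc
from .model import AdditiveRiskResults, ExplainableBoostingModel, ModelError, TrainParams

__all__ = [
    "SelectionResult",
    "rank_across_splits",
    "rank_pairs_across_splits",
    "greedy_select",
    "tune_parameters",
]


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Outcome of one greedy selection pass."""

    candidates: pd.DataFrame  # ordered; columns: candidate, mean_importance, per-split imps
    k_star: int
    trace: pd.DataFrame  # k, val_pr_auc
    results: AdditiveRiskResults
    dimension: int = 1


def _fit_split(
    X: pd.DataFrame,
    y: np.ndarray,
    split: Split,
    params: TrainParams,
    features: Sequence[str] | None = None,
) -> AdditiveRiskResults:
    """Fit on a split's train partition (its random validation part drives
    early stopping via the params' internal fraction)."""
    idx = np.concatenate([split.train_idx, split.val_idx])
    ytr = y[idx]
    if len(np.unique(ytr)) < 2:
        raise SelectionError(f"{split.name}: training labels are single-class")
    frac = len(split.val_idx) / len(idx) if len(idx) else 0.0
    p = TrainParams(**{**_pdict(params), "validation_fraction": frac, "n_bags": 1})
    m = ExplainableBoostingModel(ytr, X.iloc[idx])
    return m.fit(p, features=features, compute_bands=False)


def _pdict(p: TrainParams) -> dict:
    return {
        "max_bins_1d": p.max_bins_1d,
        "max_bins_2d": p.max_bins_2d,
        "learning_rate": p.learning_rate,
        "max_leaves": p.max_leaves,
        "boosting_rounds": p.boosting_rounds,
        "patience": p.patience,
        "n_bags": p.n_bags,
        "validation_fraction": p.validation_fraction,
        "seed": p.seed,
    }


def rank_across_splits(
    X: pd.DataFrame,
    y,
    plan: SplitPlan,
    params: TrainParams,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank 1D candidates by mean importance across the temporal splits.

    A full model is fitted per split; importance is computed on that
    split's training rows.  Ties break lexicographically by feature name.
    """
    if len(plan.temporal) < 2:
        raise SelectionError("need >= 2 temporal splits")
    y = np.asarray(y, dtype=float)
    feats = list(features) if features is not None else list(X.columns)
    per_split = {}
    for split in plan.temporal:
        res = _fit_split(X, y, split, params, features=feats)
        idx = np.concatenate([split.train_idx, split.val_idx])
        per_split[split.name] = res.importances(X.iloc[idx])
    imp = pd.DataFrame(per_split)
    imp["mean_importance"] = imp.mean(axis=1)
    imp = imp.sort_values(
        ["mean_importance"], ascending=False, kind="mergesort"
    )
    # stable lexicographic tie-break
    imp = imp.iloc[np.lexsort((imp.index.to_numpy(), -imp["mean_importance"].to_numpy()))]
    imp.index.name = "candidate"
    return imp.reset_index()


def rank_pairs_across_splits(
    X: pd.DataFrame,
    y,
    plan: SplitPlan,
    params: TrainParams,
    features_1d: Sequence[str],
) -> pd.DataFrame:
    """Rank all unordered pairs of the selected 1D features by their mean
    residual-fit importance across the temporal splits."""
    feats = list(features_1d)
    pairs = [(feats[i], feats[j]) for i in range(len(feats)) for j in range(i + 1, len(feats))]
    if not pairs:
        return pd.DataFrame(columns=["candidate", "mean_importance"])
    y = np.asarray(y, dtype=float)
    per_split = {}
    for split in plan.temporal:
        res = _fit_split(X, y, split, params, features=feats)
        idx = np.concatenate([split.train_idx, split.val_idx])
        m = ExplainableBoostingModel(y[idx], X.iloc[idx])
        p = TrainParams(**{**_pdict(params), "n_bags": 1})
        res2 = m.fit_interactions(res, pairs, p)
        imp = res2.importances(X.iloc[idx])
        per_split[split.name] = imp[[f"{a} x {b}" for a, b in pairs]]
    df = pd.DataFrame(per_split)
    df["mean_importance"] = df.mean(axis=1)
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["mean_importance"].to_numpy()))]
    df.index.name = "candidate"
    return df.reset_index()


def greedy_select(
    candidates: pd.DataFrame,
    cap: int,
    X: pd.DataFrame,
    y,
    full_split: Split,
    params: TrainParams,
    dimension: int = 1,
    base_results: AdditiveRiskResults | None = None,
) -> SelectionResult:
    """Retrain with the top-k candidates for k = 1..cap and keep the k with
    the best full-split validation PR-AUC (smallest k on ties).

    ``cap`` beyond the candidate count is truncated with a warning.  For
    ``dimension == 2``, candidates are "a x b" pair names and models are
    built by adding pairs on the residuals of ``base_results``.
    """
    import warnings

    y = np.asarray(y, dtype=float)
    names = candidates["candidate"].tolist()
    if cap > len(names):
        warnings.warn(
            f"cap {cap} exceeds {len(names)} candidates; truncating", stacklevel=2
        )
        cap = len(names)
    Xtr, ytr = X.iloc[full_split.train_idx], y[full_split.train_idx]
    Xva, yva = X.iloc[full_split.val_idx], y[full_split.val_idx]
    if len(np.unique(ytr)) < 2:
        raise SelectionError("full split: training labels are single-class")

    rows = []
    best_k, best_ap, best_res = 0, -np.inf, None
    if cap == 0 or dimension == 1:
        # k = 0: intercept-only reference (not a PR-AUC competitor)
        p0 = float(ytr.mean())
        intercept_only = AdditiveRiskResults(
            intercept=float(np.log(p0 / (1 - p0))),
            risk_functions=[],
            feature_names=list(X.columns),
        )
        if cap == 0:
            return SelectionResult(
                candidates=candidates,
                k_star=0,
                trace=pd.DataFrame(columns=["k", "val_pr_auc"]),
                results=intercept_only,
                dimension=dimension,
            )

    for k in range(1, cap + 1):
        top = names[:k]
        if dimension == 1:
            m = ExplainableBoostingModel(ytr, Xtr)
            res = m.fit(params, features=top, compute_bands=False)
        else:
            if base_results is None:
                raise SelectionError("dimension=2 needs base_results (the 1D model)")
            pairs = [tuple(n.split(" x ")) for n in top]
            m = ExplainableBoostingModel(ytr, Xtr)
            res = m.fit_interactions(base_results, pairs, params)
        ap = pr_auc(res.predict(Xva, output="prob"), yva)
        rows.append({"k": k, "val_pr_auc": ap})
        if ap > best_ap + 1e-12:
            best_k, best_ap, best_res = k, ap, res

    return SelectionResult(
        candidates=candidates,
        k_star=best_k,
        trace=pd.DataFrame(rows),
        results=best_res,
        dimension=dimension,
    )


def tune_parameters(
    X: pd.DataFrame,
    y,
    full_split: Split,
    grid: Sequence[TrainParams],
    features: Sequence[str] | None = None,
) -> tuple[TrainParams, pd.DataFrame]:
    """Exhaustive grid evaluation by full-split validation PR-AUC.

    Returns the argmax configuration (first on ties, deterministic in grid
    order) and the full trace.  The published three-step protocol — tune on
    all features, approximate the top candidates, retune on those — is a
    sequence of this operation and the rank/select operations.
    """
    grid = list(grid)
    if not grid:
        raise SelectionError("empty tuning grid")
    y = np.asarray(y, dtype=float)
    Xtr, ytr = X.iloc[full_split.train_idx], y[full_split.train_idx]
    Xva, yva = X.iloc[full_split.val_idx], y[full_split.val_idx]
    rows, best, best_ap = [], None, -np.inf
    for i, params in enumerate(grid):
        try:
            m = ExplainableBoostingModel(ytr, Xtr)
            res = m.fit(params, features=features, compute_bands=False)
            ap = pr_auc(res.predict(Xva, output="prob"), yva)
        except (ModelError, SelectionError) as err:
            rows.append({"grid_index": i, "val_pr_auc": np.nan, "error": str(err)})
            continue
        rows.append({"grid_index": i, "val_pr_auc": ap, "error": ""})
        if ap > best_ap:
            best, best_ap = params, ap
    if best is None:
        raise SelectionError("no grid configuration could be fitted")
    return best, pd.DataFrame(rows)
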