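"""Temporal validation splits and the PR-AUC-first metric suite.

The primary metric is the area under the precision-recall curve, estimated
by average precision (the step-wise estimator; linear interpolation of PR
curves is biased).  ROC-AUC (Mann-Whitney concordance with half credit for
ties) and precision at fixed recall levels are reported alongside.
Uncertainty is the SD over five temporal splits — pseudo-confidence
intervals, with no distributional claim.

Splits respect calendar order: the two most recent years are reserved (the
earlier as validation, the latest as hold-out), and each of the five
temporal splits trains on an annually cut-back prefix of the remaining
years with its own random 85/15 train/validation partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

__all__ = [
    "Split",
    "SplitPlan",
    "make_temporal_splits",
    "pr_auc",
    "roc_auc",
    "precision_at_recall",
    "evaluate_model",
    "EvalReport",
    "fit_gbm_baseline",
]

DEFAULT_RECALLS = (0.4, 0.5, 0.6, 0.8)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    return y


def pr_auc(scores, labels) -> float:
    """Average-precision estimate of the area under the PR curve.

    Step-wise (no linear interpolation); tied scores are processed as one
    threshold block.
    """
    y = _check_binary(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney concordance probability with half credit for ties."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def precision_at_recall(scores, labels, r: float) -> float:
    """Maximum precision over thresholds achieving recall >= r."""
    if not (0.0 < r <= 1.0):
        raise EvaluationError("recall level must be in (0, 1]")
    y = _check_binary(labels)
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores, dtype=float))
    ok = recall >= r
    if not ok.any():  # unreachable for r <= 1 with >= 1 positive
        raise EvaluationError(f"recall {r} unreachable")
    return float(precision[ok].max())


# ---------------------------------------------------------------------------
# temporal splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    name: str
    train_idx: np.ndarray
    val_idx: np.ndarray
    eval_idx: np.ndarray

    def disjoint(self) -> bool:
        a, b, c = map(set, (self.train_idx, self.val_idx, self.eval_idx))
        return not (a & b or a & c or b & c)


@dataclass
class SplitPlan:
    full: Split
    temporal: list[Split]
    seed: int
    year_boundaries: dict = field(default_factory=dict)


def make_temporal_splits(
    years,
    n_splits: int = 5,
    holdout_years: int = 2,
    val_fraction: float = 0.15,
    seed: int = 0,
    eval_mode: str = "holdout",
) -> SplitPlan:
    """Build the full split and ``n_splits`` annually cut-back splits.

    ``years`` is the calendar year of each stay (admission year).  The full
    split reserves the two most recent years — the earlier as validation,
    the latest as hold-out — and trains on everything before.  Temporal
    split i (i = 0..n-1) takes the training years cut back by i further
    years, partitioned 85/15 at random (seeded); its evaluation set is the
    reserved years (``eval_mode="holdout"``) or the single following year
    (``eval_mode="following"``).
    """
    yrs = np.asarray(years)
    uniq = np.sort(np.unique(yrs))
    if len(uniq) < n_splits + holdout_years:
        raise EvaluationError(
            f"need >= {n_splits + holdout_years} distinct years, got {len(uniq)}"
        )
    if eval_mode not in ("holdout", "following"):
        raise EvaluationError(f"unknown eval_mode {eval_mode!r}")
    reserved = uniq[-holdout_years:]
    last_train_year = uniq[len(uniq) - holdout_years - 1]
    rng = np.random.default_rng(seed)

    def partition(pool: np.ndarray, r: np.random.Generator):
        perm = r.permutation(pool)
        n_val = max(1, int(round(val_fraction * len(pool))))
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])

    full_pool = np.flatnonzero(yrs <= last_train_year)
    if holdout_years >= 2:
        full_train = full_pool
        full_val = np.flatnonzero(yrs == reserved[0])
        full_eval = np.flatnonzero(np.isin(yrs, reserved[1:]))
    else:
        full_train, full_val = partition(full_pool, rng)
        full_eval = np.flatnonzero(np.isin(yrs, reserved))
    full = Split("full", full_train, full_val, full_eval)

    temporal = []
    # hold-out = the reserved years minus the validation year
    eval_reserved = full_eval
    for i in range(n_splits):
        cut = last_train_year - i
        pool = np.flatnonzero(yrs <= cut)
        if len(pool) < 2:
            raise EvaluationError(f"temporal split {i} has an empty training pool")
        tr, va = partition(pool, np.random.default_rng(seed + 1000 + i))
        if eval_mode == "holdout":
            ev = eval_reserved
        else:
            nxt = uniq[np.searchsorted(uniq, cut) + 1]
            ev = np.flatnonzero(yrs == nxt)
        temporal.append(Split(f"temporal_{i}", tr, va, ev))

    return SplitPlan(
        full=full,
        temporal=temporal,
        seed=seed,
        year_boundaries={
            "last_train_year": int(last_train_year),
            "reserved_years": [int(v) for v in reserved],
        },
    )


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-split metrics with mean +- SD over the temporal splits."""

    per_split: pd.DataFrame  # index split name, columns metric names
    mean: pd.Series
    sd: pd.Series
    curves: dict  # split name -> {"precision": [...], "recall": [...]}

    def summary(self) -> str:
        lines = ["Evaluation (mean +- SD over temporal splits)"]
        for m in self.per_split.columns:
            lines.append(f"  {m:<22s} {self.mean[m]:.3f} +- {self.sd[m]:.3f}")
        return "\n".join(lines)


def _as_scorer(model) -> Callable[[pd.DataFrame], np.ndarray]:
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "predict"):
        return lambda X: np.asarray(model.predict(X, output="prob"))
    raise EvaluationError("cannot interpret model as a scorer")


def evaluate_model(
    model,
    plan: SplitPlan,
    X: pd.DataFrame,
    y,
    refit: Callable[[pd.DataFrame, np.ndarray, np.ndarray], object] | None = None,
    recalls: Sequence[float] = DEFAULT_RECALLS,
) -> EvalReport:
    """Score the evaluation set of every temporal split.

    ``model`` is anything scoreable (fitted results object, sklearn
    classifier, or a callable returning scores).  With ``refit`` given —
    a callable ``(X_train, y_train, val_idx_local) -> scoreable`` — the
    model is refit on each temporal split's training partition, which is
    what gives the SD across splits its meaning as a stability measure.
    """
    y = np.asarray(y)
    rows, curves = {}, {}
    for split in plan.temporal:
        if refit is not None:
            scorer = _as_scorer(refit(X.iloc[split.train_idx], y[split.train_idx], split.val_idx))
        else:
            scorer = _as_scorer(model)
        try:
            s = scorer(X.iloc[split.eval_idx])
            ye = y[split.eval_idx]
            metrics = {
                "pr_auc": pr_auc(s, ye),
                "roc_auc": roc_auc(s, ye),
            }
            for r in recalls:
                metrics[f"precision_at_recall_{r}"] = precision_at_recall(s, ye, r)
            p, rec, _ = precision_recall_curve(ye, s)
            curves[split.name] = {"precision": p.tolist(), "recall": rec.tolist()}
        except EvaluationError as err:
            raise EvaluationError(f"{split.name}: {err}") from err
        rows[split.name] = metrics
    per_split = pd.DataFrame(rows).T
    return EvalReport(
        per_split=per_split,
        mean=per_split.mean(axis=0),
        sd=per_split.std(axis=0, ddof=1),
        curves=curves,
    )


# ---------------------------------------------------------------------------
# black-box comparator
# ---------------------------------------------------------------------------

def fit_gbm_baseline(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    val_idx: np.ndarray | None = None,
    grid: Sequence[dict] | None = None,
    **kwargs,
):
    """Gradient-boosted tree comparator (handles NaN natively).

    With ``val_idx`` and a parameter ``grid``, the configuration with the
    best validation PR-AUC is kept; otherwise a single fit with sensible
    defaults.  Returns the fitted sklearn estimator.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise EvaluationError("labels are single-class")
    base = dict(learning_rate=0.1, max_iter=300, max_leaf_nodes=31,
                early_stopping=True, validation_fraction=0.15, random_state=seed)
    base.update(kwargs)
    if grid is None or val_idx is None:
        clf = HistGradientBoostingClassifier(**base)
        clf.fit(X, y)
        return clf
    mask = np.zeros(len(y), dtype=bool)
    mask[val_idx] = True
    best, best_ap = None, -np.inf
    for cfg in grid:
        params = {**base, **cfg}
        clf = HistGradientBoostingClassifier(**params)
        clf.fit(X.loc[~mask], y[~mask])
        ap = pr_auc(clf.predict_proba(X.loc[mask])[:, 1], y[mask])
        if ap > best_ap:
            best, best_ap = clf, ap
    return best
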