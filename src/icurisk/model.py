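"""Editable additive risk models fitted by cyclic gradient boosting.

The model is a generalized additive model on the logit scale,

    logit p = beta0 + sum_i f_i(x_i) + sum_{i<j} f_ij(x_i, x_j),

whose shape functions ("risk functions") are piecewise-constant lookup
tables over quantile bins, estimated by cyclic gradient boosting: every
boosting round visits each feature in a fixed order and adds a shrunken
depth-limited regression-tree fit of the current log-loss gradient on that
feature's bins.  Because each feature is pre-binned, the tree reduces to an
exact search over contiguous bin partitions; the missing bin is a separate,
trainable level.  After fitting, each risk function is centred to mean zero
over the training histogram (the displaced mass moves into the intercept),
so bin scores read directly as log-odds contributions relative to the
average patient.

Usage follows the statsmodels convention: build an
:class:`ExplainableBoostingModel` from data, call :meth:`fit` and work with
the returned :class:`AdditiveRiskResults`, which carries the intercept, the
risk functions with confidence bands and training histograms, per-row
contribution breakdowns, importances, an edit log, and lossless JSON
serialization.
"""

from __future__ import annotations

import copy
import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinScheme",
    "RiskFunction",
    "TrainParams",
    "ExplainableBoostingModel",
    "AdditiveRiskResults",
    "bin_feature",
]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Right-closed quantile bins for one feature, plus a missing bin.

    Finite bin ``i`` covers ``(cuts[i-1], cuts[i]]`` (unbounded at the
    edges); missing values map to the dedicated last bin.
    """

    feature: str
    cuts: tuple[float, ...]  # strictly increasing interior cut points

    def __post_init__(self) -> None:
        c = np.asarray(self.cuts, dtype=float)
        if c.size and not np.all(np.diff(c) > 0):
            raise ModelError(f"cut points must be strictly increasing for {self.feature!r}")

    @property
    def n_finite(self) -> int:
        return len(self.cuts) + 1

    @property
    def n_bins(self) -> int:
        """Finite bins plus the missing bin."""
        return self.n_finite + 1

    @property
    def missing_index(self) -> int:
        return self.n_finite

    def codes(self, values: np.ndarray) -> np.ndarray:
        """Map values to bin indices; NaN goes to the missing bin."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts, dtype=float), v, side="left")
        return np.where(np.isnan(v), self.missing_index, idx).astype(np.intp)


def bin_feature(values: np.ndarray, max_bins: int) -> BinScheme:
    """Quantile-bin a feature into at most ``max_bins`` non-empty bins.

    Duplicate quantiles collapse; cut points at or above the maximum are
    dropped so no trailing bin is empty.  An all-missing feature yields a
    scheme with a single finite bin (which no finite value will use) plus
    the missing bin.
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    name = getattr(values, "name", None) or "feature"
    if finite.size == 0:
        return BinScheme(str(name), ())
    if max_bins < 1:
        raise ModelError("max_bins must be >= 1")
    qs = np.linspace(0, 1, max_bins + 1)[1:-1]
    cuts = np.unique(np.quantile(finite, qs))
    cuts = cuts[cuts < finite.max()]
    cuts = cuts[cuts >= finite.min()]
    return BinScheme(str(name), tuple(float(c) for c in cuts))


# ---------------------------------------------------------------------------
# risk functions
# ---------------------------------------------------------------------------

@dataclass
class RiskFunction:
    """One binned shape function: log-odds per bin with CI and histogram.

    1D functions hold a flat score vector of length ``bins[0].n_bins``;
    2D functions hold a grid of shape ``(bins[0].n_bins, bins[1].n_bins)``
    flattened row-major.  Scores are mean-zero under the training histogram.
    """

    features: tuple[str, ...]
    bins: tuple[BinScheme, ...]
    scores: np.ndarray
    ci: np.ndarray | None = None
    histogram: np.ndarray | None = None
    importance: float = 0.0

    @property
    def dim(self) -> int:
        return len(self.features)

    @property
    def name(self) -> str:
        return " x ".join(self.features)

    def codes(self, X: pd.DataFrame) -> np.ndarray:
        """Flat bin index per row of ``X``."""
        for f in self.features:
            if f not in X.columns:
                raise ModelError(f"feature {f!r} absent from input schema")
        c0 = self.bins[0].codes(X[self.features[0]].to_numpy(dtype=float))
        if self.dim == 1:
            return c0
        c1 = self.bins[1].codes(X[self.features[1]].to_numpy(dtype=float))
        return c0 * self.bins[1].n_bins + c1

    def contribution(self, X: pd.DataFrame) -> np.ndarray:
        return self.scores[self.codes(X)]

    def grid_scores(self) -> np.ndarray:
        """2D scores reshaped to (bins0, bins1)."""
        if self.dim != 2:
            raise ModelError("grid_scores is defined for 2D functions only")
        return self.scores.reshape(self.bins[0].n_bins, self.bins[1].n_bins)


# ---------------------------------------------------------------------------
# training parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainParams:
    """Hyperparameters of the cyclic boosting fit.

    ``boosting_rounds`` counts full cycles over the features; early stopping
    watches log-loss on an internal validation fraction with the given
    patience (set ``validation_fraction=0`` to disable).  ``n_bags``
    bootstrap refits define the per-bin confidence band (mean +- 1 SD).
    """

    max_bins_1d: int = 200
    max_bins_2d: int = 4
    learning_rate: float = 0.01
    max_leaves: int = 3
    boosting_rounds: int = 5000
    patience: int = 50
    n_bags: int = 8
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_bins_1d, self.max_bins_2d, self.max_leaves) <= 0:
            raise ModelError("counts must be positive")
        if self.boosting_rounds < 0:
            raise ModelError("boosting_rounds must be non-negative")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if self.max_bins_2d > self.max_bins_1d:
            raise ModelError("max_bins_2d must not exceed max_bins_1d")


# ---------------------------------------------------------------------------
# internal boosting machinery
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _logloss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _tree_update(G: np.ndarray, H: np.ndarray, n_finite: int, max_leaves: int, lr: float) -> np.ndarray:
    """One shrunken Newton tree on a binned axis.

    Finite bins are greedily partitioned into at most ``max_leaves``
    contiguous segments by exact best-split search on the squared-gradient
    gain; the missing bin is its own leaf.  Returns the per-bin score delta.
    """
    delta = np.zeros_like(G)
    if n_finite == 0:
        # categorical axis (2D grid cells): every bin is its own leaf
        nz = H > _EPS
        delta[nz] = lr * G[nz] / (H[nz] + _EPS)
        return delta
    # missing bin leaf
    if H[n_finite] > _EPS:
        delta[n_finite] = lr * G[n_finite] / (H[n_finite] + _EPS)
    segs = [(0, n_finite)]  # half-open over finite bins
    cg = np.concatenate([[0.0], np.cumsum(G[:n_finite])])
    ch = np.concatenate([[0.0], np.cumsum(H[:n_finite])])

    def seg_gain(a: int, b: int) -> tuple[float, int]:
        g, h = cg[b] - cg[a], ch[b] - ch[a]
        base = g * g / (h + _EPS)
        best, best_s = 0.0, -1
        for s in range(a + 1, b):
            gl, hl = cg[s] - cg[a], ch[s] - ch[a]
            gr, hr = cg[b] - cg[s], ch[b] - ch[s]
            gain = gl * gl / (hl + _EPS) + gr * gr / (hr + _EPS) - base
            if gain > best:
                best, best_s = gain, s
        return best, best_s

    while len(segs) < max_leaves:
        gains = [seg_gain(a, b) for a, b in segs]
        k = int(np.argmax([g for g, _ in gains]))
        gain, s = gains[k]
        if s < 0 or gain <= _EPS:
            break
        a, b = segs.pop(k)
        segs.extend([(a, s), (s, b)])
    for a, b in segs:
        g, h = cg[b] - cg[a], ch[b] - ch[a]
        if h > _EPS:
            delta[a:b] = lr * g / (h + _EPS)
    return delta


def _cyclic_boost(
    codes: np.ndarray,
    n_bins: Sequence[int],
    n_finite: Sequence[int],
    y: np.ndarray,
    params: TrainParams,
    rng: np.random.Generator,
    sample_weight: np.ndarray | None = None,
    base_logit: np.ndarray | None = None,
) -> tuple[list[np.ndarray], float]:
    """Core cyclic boosting loop over pre-binned features.

    Returns the per-feature score tables and the intercept (base rate on
    the logit scale).  ``base_logit`` freezes an offset per row (used when
    boosting 2D functions on 1D residuals).
    """
    n, d = codes.shape
    w = np.ones(n) if sample_weight is None else sample_weight
    # internal validation split for early stopping
    if params.validation_fraction > 0 and n >= 20:
        idx = rng.permutation(n)
        n_val = max(1, int(round(params.validation_fraction * n)))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
    else:
        val_idx, tr_idx = np.empty(0, np.intp), np.arange(n)

    wt = w[tr_idx]
    yt = y[tr_idx]
    if wt.sum() <= 0 or len(np.unique(yt[wt > 0])) < 2:
        raise ModelError("training labels are single-class")
    if base_logit is not None:
        # residual boosting on a frozen offset: no new base rate
        base = 0.0
        logit = base_logit.astype(float).copy()
    else:
        base = np.log((yt * wt).sum() / ((1 - yt) * wt).sum())
        logit = np.full(n, base)
    scores = [np.zeros(b) for b in n_bins]

    best_val = np.inf
    best_scores = [s.copy() for s in scores]
    since_best = 0
    for _ in range(params.boosting_rounds):
        p = _sigmoid(logit[tr_idx])
        for j in range(d):
            g = (yt - p) * wt
            h = p * (1 - p) * wt
            cj = codes[tr_idx, j]
            G = np.bincount(cj, weights=g, minlength=n_bins[j])
            H = np.bincount(cj, weights=h, minlength=n_bins[j])
            delta = _tree_update(G, H, n_finite[j], params.max_leaves, params.learning_rate)
            scores[j] += delta
            logit[tr_idx] += delta[cj]
            if len(val_idx):
                logit[val_idx] += delta[codes[val_idx, j]]
            p = _sigmoid(logit[tr_idx])
        if len(val_idx):
            vl = _logloss(y[val_idx], _sigmoid(logit[val_idx]))
            if vl < best_val - 1e-9:
                best_val = vl
                best_scores = [s.copy() for s in scores]
                since_best = 0
            else:
                since_best += 1
                if since_best >= params.patience:
                    scores = best_scores
                    break
    else:
        if len(val_idx):
            scores = best_scores
    return scores, float(base)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ExplainableBoostingModel:
    """Additive risk model specification bound to a training data set.

    Parameters
    ----------
    endog : array-like of 0/1 labels.
    exog : DataFrame of features (NaN marks missingness).
    """

    def __init__(self, endog, exog: pd.DataFrame):
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog, dtype=float))
            exog.columns = [str(c) for c in exog.columns]
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or len(y) != len(exog):
            raise ModelError("endog must be 1-D and aligned with exog")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ModelError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ModelError("labels are single-class; cannot fit a classifier")
        if exog.shape[1] < 1:
            raise ModelError("need at least one feature")
        self.endog = y
        self.exog = exog
        self.feature_names = list(exog.columns)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "ExplainableBoostingModel":
        return cls(df[label_col].to_numpy(), df.drop(columns=[label_col]))

    # -- fitting -----------------------------------------------------------

    def fit(self, params: TrainParams | None = None, features: Sequence[str] | None = None,
            compute_bands: bool = True) -> "AdditiveRiskResults":
        """Fit 1D risk functions by cyclic gradient boosting."""
        params = params or TrainParams()
        feats = list(features) if features is not None else self.feature_names
        missing = [f for f in feats if f not in self.exog.columns]
        if missing:
            raise ModelError(f"unknown features: {missing}")
        rng = np.random.default_rng(params.seed)
        schemes = [
            bin_feature(self.exog[f].rename(f), params.max_bins_1d) for f in feats
        ]
        codes = np.column_stack(
            [s.codes(self.exog[f].to_numpy(dtype=float)) for s, f in zip(schemes, feats)]
        ) if feats else np.zeros((len(self.endog), 0), dtype=np.intp)
        n_bins = [s.n_bins for s in schemes]
        n_fin = [s.n_finite for s in schemes]

        if feats:
            scores, base = _cyclic_boost(codes, n_bins, n_fin, self.endog, params, rng)
        else:
            p = self.endog.mean()
            scores, base = [], float(np.log(p / (1 - p)))

        # bagged confidence bands
        sds = None
        if compute_bands and feats and params.n_bags > 1:
            bag_scores = []
            n = len(self.endog)
            for _ in range(params.n_bags):
                wb = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
                try:
                    sb, _ = _cyclic_boost(codes, n_bins, n_fin, self.endog, params, rng, sample_weight=wb)
                except ModelError:
                    continue  # degenerate bootstrap resample
                bag_scores.append(sb)
            if len(bag_scores) >= 2:
                sds = [
                    np.std(np.stack([b[j] for b in bag_scores]), axis=0)
                    for j in range(len(feats))
                ]

        functions: list[RiskFunction] = []
        intercept = base
        for j, f in enumerate(feats):
            hist = np.bincount(codes[:, j], minlength=n_bins[j]).astype(float)
            sc = scores[j].copy()
            mean = float(np.average(sc, weights=hist)) if hist.sum() else 0.0
            sc -= mean
            intercept += mean
            contrib = sc[codes[:, j]]
            functions.append(
                RiskFunction(
                    features=(f,),
                    bins=(schemes[j],),
                    scores=sc,
                    ci=(sds[j] if sds is not None else None),
                    histogram=hist,
                    importance=float(np.mean(np.abs(contrib))),
                )
            )
        meta = {
            "params": _params_dict(params),
            "seed": params.seed,
            "n_train": int(len(self.endog)),
            "fitted_at": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        }
        return AdditiveRiskResults(
            intercept=float(intercept),
            risk_functions=functions,
            feature_names=list(self.exog.columns),
            metadata=meta,
            model=self,
        )

    def fit_interactions(
        self,
        results: "AdditiveRiskResults",
        pairs: Sequence[tuple[str, str]],
        params: TrainParams | None = None,
    ) -> "AdditiveRiskResults":
        """Add 2D risk functions boosted on the residuals of ``results``.

        The 1D functions stay frozen; each pair's score grid (at most
        ``max_bins_2d`` bins per axis, plus missing) is boosted against the
        residual log-loss gradient.  Returns a new results object.
        """
        params = params or TrainParams()
        fitted_feats = {f.features[0] for f in results.risk_functions if f.dim == 1}
        for a, b in pairs:
            for f in (a, b):
                if f not in fitted_feats:
                    raise ModelError(f"pair references feature {f!r} not in the 1D model")
        if not pairs:
            return results
        rng = np.random.default_rng(params.seed + 1)
        base_logit = results.predict(self.exog, output="logit")
        X = self.exog
        schemes2, codes_cols, n_bins, n_fin = [], [], [], []
        for a, b in pairs:
            sa = bin_feature(X[a].rename(a), params.max_bins_2d)
            sb = bin_feature(X[b].rename(b), params.max_bins_2d)
            ca = sa.codes(X[a].to_numpy(dtype=float))
            cb = sb.codes(X[b].to_numpy(dtype=float))
            schemes2.append((sa, sb))
            codes_cols.append(ca * sb.n_bins + cb)
            n_bins.append(sa.n_bins * sb.n_bins)
            n_fin.append(0)  # every cell is its own categorical leaf
        codes = np.column_stack(codes_cols)

        scores, _ = _cyclic_boost(
            codes, n_bins, [0] * len(pairs), self.endog, params, rng, base_logit=base_logit
        )
        new = results._copy()
        for k, (a, b) in enumerate(pairs):
            hist = np.bincount(codes[:, k], minlength=n_bins[k]).astype(float)
            sc = scores[k].copy()
            mean = float(np.average(sc, weights=hist)) if hist.sum() else 0.0
            sc -= mean
            new.intercept += mean
            contrib = sc[codes[:, k]]
            new.risk_functions.append(
                RiskFunction(
                    features=(a, b),
                    bins=schemes2[k],
                    scores=sc,
                    ci=None,
                    histogram=hist,
                    importance=float(np.mean(np.abs(contrib))),
                )
            )
        return new


def _params_dict(p: TrainParams) -> dict:
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


@dataclass
class AdditiveRiskResults:
    """A fitted, editable additive risk model.

    The prediction decomposes exactly as ``intercept + sum of per-function
    contributions``; :meth:`contributions` exposes every addend, which is
    both the per-prediction explanation and the lever for model editing.
    """

    intercept: float
    risk_functions: list[RiskFunction]
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)
    edit_log: list[dict] = field(default_factory=list)
    model: "ExplainableBoostingModel | None" = None

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame, output: str = "prob") -> np.ndarray:
        logit = np.full(len(X), self.intercept)
        for rf in self.risk_functions:
            logit = logit + rf.contribution(X)
        if output == "logit":
            return logit
        if output == "prob":
            return _sigmoid(logit)
        raise ModelError(f"unknown output {output!r}")

    def contributions(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-row additive breakdown: one column per risk function plus
        the intercept; rows sum exactly to the logit."""
        data = {"intercept": np.full(len(X), self.intercept)}
        for rf in self.risk_functions:
            data[rf.name] = rf.contribution(X)
        return pd.DataFrame(data, index=X.index)

    # -- importance --------------------------------------------------------

    def importances(self, X: pd.DataFrame | None = None, relative: bool = False) -> pd.Series:
        """Mean absolute log-odds contribution per risk function.

        With ``X`` given, importances are recomputed on those reference
        rows; otherwise the training-time values are reported.  With
        ``relative=True`` they are normalised to sum to 100.
        """
        if X is not None:
            vals = {rf.name: float(np.mean(np.abs(rf.contribution(X)))) for rf in self.risk_functions}
        else:
            vals = {rf.name: rf.importance for rf in self.risk_functions}
        s = pd.Series(vals, dtype=float)
        if relative:
            total = s.sum()
            s = s * (100.0 / total) if total > 0 else s
        return s

    # -- editing -----------------------------------------------------------

    def _copy(self) -> "AdditiveRiskResults":
        return AdditiveRiskResults(
            intercept=self.intercept,
            risk_functions=[copy.deepcopy(rf) for rf in self.risk_functions],
            feature_names=list(self.feature_names),
            metadata=copy.deepcopy(self.metadata),
            edit_log=copy.deepcopy(self.edit_log),
            model=self.model,
        )

    def function_names(self) -> list[str]:
        return [rf.name for rf in self.risk_functions]

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        imp = self.importances()
        rel = self.importances(relative=True)
        lines = [
            "Additive risk model (logit link)",
            f"  intercept (log-odds): {self.intercept:+.4f}",
            f"  risk functions: {len(self.risk_functions)} "
            f"({sum(rf.dim == 1 for rf in self.risk_functions)} 1D, "
            f"{sum(rf.dim == 2 for rf in self.risk_functions)} 2D)",
            f"  edits applied: {len(self.edit_log)}",
            "",
            f"  {'risk function':<45s} {'dim':>3s} {'bins':>5s} {'importance':>11s} {'rel %':>6s}",
        ]
        order = imp.sort_values(ascending=False).index
        by_name = {rf.name: rf for rf in self.risk_functions}
        for name in order:
            rf = by_name[name]
            nb = int(np.prod([b.n_bins for b in rf.bins]))
            lines.append(
                f"  {name:<45s} {rf.dim:>3d} {nb:>5d} {imp[name]:>11.4f} {rel[name]:>6.2f}"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "functions": [
                {
                    "features": list(rf.features),
                    "cuts": [list(b.cuts) for b in rf.bins],
                    "scores": rf.scores.tolist(),
                    "ci": (rf.ci.tolist() if rf.ci is not None else None),
                    "histogram": (rf.histogram.tolist() if rf.histogram is not None else None),
                    "importance": rf.importance,
                }
                for rf in self.risk_functions
            ],
            "feature_names": self.feature_names,
            "metadata": self.metadata,
            "edit_log": self.edit_log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "AdditiveRiskResults":
        funcs = []
        for fd in d["functions"]:
            feats = tuple(fd["features"])
            bins = tuple(
                BinScheme(f, tuple(c)) for f, c in zip(feats, fd["cuts"])
            )
            funcs.append(
                RiskFunction(
                    features=feats,
                    bins=bins,
                    scores=np.asarray(fd["scores"], dtype=float),
                    ci=(np.asarray(fd["ci"], dtype=float) if fd["ci"] is not None else None),
                    histogram=(
                        np.asarray(fd["histogram"], dtype=float)
                        if fd["histogram"] is not None else None
                    ),
                    importance=float(fd["importance"]),
                )
            )
        return cls(
            intercept=float(d["intercept"]),
            risk_functions=funcs,
            feature_names=list(d["feature_names"]),
            metadata=d.get("metadata", {}),
            edit_log=list(d.get("edit_log", [])),
        )

    @classmethod
    def from_json(cls, s: str) -> "AdditiveRiskResults":
        return cls.from_dict(json.loads(s))

    @classmethod
    def load(cls, path: str) -> "AdditiveRiskResults":
        with open(path) as fh:
            return cls.from_json(fh.read())
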