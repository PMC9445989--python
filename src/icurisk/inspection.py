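"""Human-in-the-loop inspection and editing of additive risk models.

Risk functions are rendered one by one (step curve of bin scores with its
confidence band over an aligned training histogram; the missing bin shown
as a separate "unknown" level) and reviewed against a fixed a-priori
problem taxonomy:

* ``disparity`` — the function encodes a disparity the model should not act on;
* ``data_artifact`` — the shape reflects a measurement or documentation
  artifact rather than physiology (e.g. an assay change in a late year);
* ``contradicts_knowledge`` — the shape contradicts medical knowledge;
* ``not_interpretable`` — the reviewers cannot form an intuition for it.

Each function gets exactly one decision — include clean, include with
problems, or exclude — recorded with free-text justification, reviewer and
timestamp.  Excluded functions are then removed from the additive sum;
because the model is exactly additive, removal changes each prediction by
precisely that function's contribution, and the intercept is left alone
(an optional flag refits the intercept only).  Edits are non-destructive
and logged on the returned model.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import AdditiveRiskResults, ModelError, RiskFunction, _sigmoid

__all__ = [
    "PROBLEM_TAXONOMY",
    "DECISIONS",
    "InspectionRecord",
    "InspectionLedger",
    "render_function",
    "record_inspection",
    "remove_functions",
]

PROBLEM_TAXONOMY = ("disparity", "data_artifact", "contradicts_knowledge", "not_interpretable")
DECISIONS = ("include_clean", "include_with_problems", "exclude")


class InspectionError(ValueError):
    pass


@dataclass(frozen=True)
class InspectionRecord:
    """One reviewed risk function."""

    function_id: str
    problems: tuple[str, ...] = ()
    decision: str = "include_clean"
    note: str = ""
    reviewer: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.problems) - set(PROBLEM_TAXONOMY)
        if unknown:
            raise InspectionError(f"unknown problems {sorted(unknown)}")
        if self.decision not in DECISIONS:
            raise InspectionError(f"unknown decision {self.decision!r}")
        if self.decision == "exclude" and not self.problems:
            raise InspectionError("exclusion requires at least one recorded problem")
        if self.decision == "include_clean" and self.problems:
            raise InspectionError("include_clean forbids recorded problems")


@dataclass
class InspectionLedger:
    records: list[InspectionRecord]

    def tally_by_decision(self) -> dict[str, int]:
        return {d: sum(r.decision == d for r in self.records) for d in DECISIONS}

    def tally_by_problem(self) -> dict[str, int]:
        return {p: sum(p in r.problems for r in self.records) for p in PROBLEM_TAXONOMY}

    def excluded_ids(self) -> list[str]:
        return [r.function_id for r in self.records if r.decision == "exclude"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "function_id": [r.function_id for r in self.records],
                "problems": [";".join(r.problems) for r in self.records],
                "decision": [r.decision for r in self.records],
                "note": [r.note for r in self.records],
                "reviewer": [r.reviewer for r in self.records],
                "timestamp": [r.timestamp for r in self.records],
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "InspectionLedger":
        df = pd.read_csv(path, keep_default_na=False)
        records = [
            InspectionRecord(
                function_id=row["function_id"],
                problems=tuple(p for p in str(row["problems"]).split(";") if p),
                decision=row["decision"],
                note=str(row.get("note", "")),
                reviewer=str(row.get("reviewer", "")),
                timestamp=str(row.get("timestamp", "")),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def function_table(rf: RiskFunction) -> pd.DataFrame:
    """Tabular dump: one row per bin (interval, score, CI, count)."""
    if rf.dim == 2:
        rows = []
        g = rf.grid_scores()
        h = (rf.histogram.reshape(g.shape) if rf.histogram is not None else np.zeros(g.shape))
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                rows.append(
                    {
                        "bin": f"{_bin_label(rf.bins[0], i)} x {_bin_label(rf.bins[1], j)}",
                        "score": g[i, j],
                        "ci": np.nan,
                        "count": h[i, j],
                    }
                )
        return pd.DataFrame(rows)
    labels = [_bin_label(rf.bins[0], i) for i in range(rf.bins[0].n_bins)]
    return pd.DataFrame(
        {
            "bin": labels,
            "score": rf.scores,
            "ci": (rf.ci if rf.ci is not None else np.full(len(labels), np.nan)),
            "count": (rf.histogram if rf.histogram is not None else np.zeros(len(labels))),
        }
    )


def _bin_label(scheme, i: int) -> str:
    if i == scheme.missing_index:
        return "(unknown)"
    cuts = scheme.cuts
    lo = "-inf" if i == 0 else f"{cuts[i - 1]:.4g}"
    hi = "+inf" if i == len(cuts) else f"{cuts[i]:.4g}"
    return f"({lo}, {hi}]"


def render_function(rf: RiskFunction, path: str | None = None):
    """Render a risk function as a step curve with CI band and histogram.

    Returns ``(figure, table)``; the figure is also written to ``path``
    when given.  The missing bin is drawn as a separate level labelled
    "(unknown)".
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rf.scores.size < 1:
        raise InspectionError("risk function has no bins")
    table = function_table(rf)

    if rf.dim == 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        g = rf.grid_scores()
        im = ax.imshow(g, cmap="RdBu_r", aspect="auto")
        fig.colorbar(im, ax=ax, label="log-odds")
        ax.set_xlabel(rf.features[1])
        ax.set_ylabel(rf.features[0])
        ax.set_title(rf.name)
    else:
        fig, (ax, axh) = plt.subplots(
            2, 1, sharex=False, figsize=(6, 5), height_ratios=[3, 1]
        )
        n_fin = rf.bins[0].n_finite
        xs = np.arange(n_fin + 1)
        ys = rf.scores[:n_fin]
        ax.step(xs, np.append(ys, ys[-1]), where="post", color="C0")
        if rf.ci is not None:
            ci = rf.ci[:n_fin]
            ax.fill_between(
                xs, np.append(ys - ci, (ys - ci)[-1]), np.append(ys + ci, (ys + ci)[-1]),
                step="post", alpha=0.25, color="C0",
            )
        # the missing bin as its own labelled level
        miss = rf.bins[0].missing_index
        ax.hlines(rf.scores[miss], n_fin + 0.5, n_fin + 1.5, color="C3")
        ax.annotate("(unknown)", (n_fin + 0.5, rf.scores[miss]), fontsize=8)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_ylabel("log-odds contribution")
        ax.set_title(rf.name)
        if rf.histogram is not None:
            axh.bar(np.arange(len(rf.histogram)), rf.histogram, color="grey")
        axh.set_ylabel("n")
        axh.set_xlabel(f"{rf.features[0]} (bin index; last = unknown)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig, table


# ---------------------------------------------------------------------------
# recording & editing
# ---------------------------------------------------------------------------

def record_inspection(
    results: AdditiveRiskResults, records: Iterable[InspectionRecord]
) -> InspectionLedger:
    """Validate and collect one record per risk function.

    Every function must be reviewed exactly once; unknown or duplicate
    function ids fail with the offending ids listed.
    """
    records = list(records)
    names = results.function_names()
    seen: dict[str, int] = {}
    for r in records:
        seen[r.function_id] = seen.get(r.function_id, 0) + 1
    unknown = sorted(set(seen) - set(names))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    missing = sorted(set(names) - set(seen))
    if unknown or dupes or missing:
        raise InspectionError(
            f"bad inspection records — unknown: {unknown}; duplicates: {dupes}; "
            f"missing: {missing}"
        )
    return InspectionLedger(records)


def remove_functions(
    results: AdditiveRiskResults,
    ids: Sequence[str],
    ledger_ref: str = "",
    recalibrate: bool = False,
) -> AdditiveRiskResults:
    """Delete the listed risk functions; returns an edited copy.

    The intercept is left untouched (set ``recalibrate=True`` to refit
    only the intercept on the training data, if available).  Unknown ids
    fail before any change; the original object is never modified.  The
    edit is appended to the model's edit log with a timestamp.
    """
    ids = list(ids)
    names = results.function_names()
    unknown = sorted(set(ids) - set(names))
    if unknown:
        raise ModelError(f"cannot remove unknown risk functions: {unknown}")
    new = results._copy()
    new.risk_functions = [rf for rf in new.risk_functions if rf.name not in set(ids)]
    new.edit_log.append(
        {
            "action": "remove_functions",
            "ids": sorted(ids),
            "ledger_ref": ledger_ref,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        }
    )
    if recalibrate:
        if results.model is None:
            raise ModelError("recalibration needs the training data on the results object")
        X, y = results.model.exog, results.model.endog
        offset = new.predict(X, output="logit") - new.intercept
        from scipy.optimize import brentq

        def f(b0):
            return float(_sigmoid(b0 + offset).mean() - y.mean())

        new.intercept = float(brentq(f, -30, 30))
        new.edit_log[-1]["recalibrated_intercept"] = new.intercept
    return new
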