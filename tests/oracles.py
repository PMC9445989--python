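"""Independent brute-force oracles used across the test suite.

Everything here is written from first principles (loops, exhaustive
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAY = pd.Timedelta(days=1)
WINDOW_HOURS = {"4h": 4, "12h": 12, "24h": 24, "1d": 24, "3d": 72, "7d": 168}
HORIZON_WINDOWS = {
    "high": ("4h", "12h", "24h"),
    "medium": ("12h", "24h", "3d"),
    "low": ("1d", "3d", "7d"),
}


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def in_window(ts, discharge, window):
    w = pd.Timedelta(hours=WINDOW_HOURS[window])
    return (ts > discharge - w) and (ts <= discharge)


def naive_timeseries(rows, discharge, horizon):
    """rows: list of (timestamp, value). Returns {(stat, window): value}."""
    out = {}
    for window in HORIZON_WINDOWS[horizon]:
        pts = [(t, v) for t, v in rows if in_window(t, discharge, window)]
        if not pts:
            for s in ("median", "iqr", "min", "max", "trend_per_day"):
                out[(s, window)] = np.nan
            continue
        vals = np.array([v for _, v in pts], dtype=float)
        out[("median", window)] = float(np.median(vals))
        q75, q25 = np.percentile(vals, 75), np.percentile(vals, 25)
        out[("iqr", window)] = float(q75 - q25)
        out[("min", window)] = float(vals.min())
        out[("max", window)] = float(vals.max())
        if len(pts) < 2:
            out[("trend_per_day", window)] = np.nan
        else:
            t0 = min(t for t, _ in pts)
            x = np.array([(t - t0) / DAY for t, _ in pts], dtype=float)
            if np.allclose(x, x[0]):
                out[("trend_per_day", window)] = np.nan
            else:
                slope = np.polyfit(x, vals, 1)[0]
                out[("trend_per_day", window)] = float(slope)
    return out


def naive_flow(rows, discharge):
    out = {}
    for window in ("1d", "3d", "7d"):
        total = sum(v for t, v in rows if in_window(t, discharge, window))
        out[window] = total * 24.0 / WINDOW_HOURS[window]
    return out


def naive_medication(rows, discharge):
    out = {}
    for window in ("1d", "3d", "7d"):
        drugs = {v for t, v in rows if in_window(t, discharge, window)}
        out[("indicator", window)] = float(len(drugs) > 0)
        out[("unique_count", window)] = float(len(drugs))
    return out


def naive_intervention(rows, discharge):
    out = {}
    for window in ("3d", "7d"):
        out[("indicator", window)] = float(
            any(in_window(t, discharge, window) for t, _ in rows)
        )
    pre = [(t, v) for t, v in rows if t <= discharge]
    if pre:
        last_t = max(t for t, _ in pre)
        out[("days_since_last", "history")] = float((discharge - last_t) / DAY)
        out[("last_value", "history")] = float([v for t, v in pre if t == last_t][0])
    else:
        out[("days_since_last", "history")] = np.nan
        out[("last_value", "history")] = np.nan
    return out


def naive_static(rows, discharge, start=None):
    pre = [(t, v) for t, v in rows if t <= discharge and (start is None or t >= start)]
    if not pre:
        return np.nan
    last_t = max(t for t, _ in pre)
    return float([v for t, v in pre if t == last_t][0])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def ap_bruteforce(scores, labels):
    """Average precision by explicit threshold enumeration with tie blocks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    thresholds = np.unique(scores)[::-1]
    ap, prev_recall = 0.0, 0.0
    for th in thresholds:
        sel = scores >= th
        tp = int(labels[sel].sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def roc_bruteforce(scores, labels):
    """Pairwise concordance with half credit for ties (O(n^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def precision_at_recall_bruteforce(scores, labels, r):
    """Max precision over every threshold achieving recall >= r."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    best = 0.0
    for th in np.unique(scores):
        sel = scores >= th
        tp = int(labels[sel].sum())
        if tp / n_pos >= r:
            best = max(best, tp / sel.sum())
    return best


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def count_stays_linear_scan(intervals, gap_threshold):
    """Expected stay count for one patient's sorted (admit, discharge) list."""
    if not intervals:
        return 0
    count = 1
    prev_end = intervals[0][1]
    for a, d in intervals[1:]:
        if (a - prev_end) > gap_threshold:
            count += 1
        prev_end = max(prev_end, d)
    return count
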