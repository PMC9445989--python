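"""Engineered features from per-stay event histories.

Variables fall into five classes (time series, patient flow, medication,
intervention, static).  Time-series variables are summarised by windowed
descriptive statistics (median, IQR, min, max, linear trend) over three
lookback windows whose lengths depend on the variable's *time horizon* —
high / medium / low, assigned from the median sampling interval.  Flows are
extrapolated to daily rates, medications yield administration indicators and
unique-drug counts, interventions yield indicators plus the interval since
last performed, and static variables contribute their last recorded value.

All windows end at ICU discharge and are right-closed: an event at timestamp
``t`` belongs to the window of length ``w`` iff ``discharge - w < t <=
discharge``.  Events after discharge are always ignored (featurization is
causal).  Missing values stay missing (NaN); the downstream additive model
owns a dedicated missing bin, so nothing is imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)
DAY = pd.Timedelta(days=1)

#: lookback windows per horizon, shortest first
HORIZON_WINDOWS: dict[str, tuple[str, ...]] = {
    "high": ("4h", "12h", "24h"),
    "medium": ("12h", "24h", "3d"),
    "low": ("1d", "3d", "7d"),
}

WINDOW_HOURS: dict[str, float] = {
    "4h": 4.0,
    "12h": 12.0,
    "24h": 24.0,
    "1d": 24.0,
    "3d": 72.0,
    "7d": 168.0,
}

TIMESERIES_STATS = ("median", "iqr", "min", "max", "trend_per_day")
FLOW_WINDOWS = ("1d", "3d", "7d")
MEDICATION_WINDOWS = ("1d", "3d", "7d")
INTERVENTION_WINDOWS = ("3d", "7d")

VARIABLE_CLASSES = ("timeseries", "flow", "medication", "intervention", "static")
STATIC_INTERVALS = ("patient", "hospital_stay", "icu_stay")

#: name of the manually added feature (days on ward/hospital before ICU admission)
MANUAL_LOS_FEATURE = "length_of_stay_before_icu"


class FeaturizeError(ValueError):
    """Raised on malformed event data or variable specs."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares how one variable is featurized.

    ``horizon`` is only meaningful for time-series variables; flows,
    medications and interventions are always treated as low horizon, and
    static variables have no horizon at all.
    """

    variable_id: str
    var_class: str
    horizon: str = "auto"  # auto | high | medium | low
    static_interval: str = "icu_stay"

    def __post_init__(self) -> None:
        if self.var_class not in VARIABLE_CLASSES:
            raise FeaturizeError(
                f"unknown variable class {self.var_class!r} for {self.variable_id!r}"
            )
        if self.horizon not in ("auto", "high", "medium", "low"):
            raise FeaturizeError(f"unknown horizon {self.horizon!r}")
        if self.static_interval not in STATIC_INTERVALS:
            raise FeaturizeError(f"unknown static interval {self.static_interval!r}")


@dataclass(frozen=True)
class FeatureDescriptor:
    """(variable, statistic, window) triple naming one feature column."""

    variable_id: str
    statistic: str
    window: str

    @property
    def name(self) -> str:
        return f"{self.variable_id}|{self.statistic}|{self.window}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @staticmethod
    def parse(name: str) -> "FeatureDescriptor":
        var, stat, window = name.split("|")
        return FeatureDescriptor(var, stat, window)


@dataclass
class FeatureMatrix:
    """Stays x engineered features with explicit missingness (NaN)."""

    df: pd.DataFrame  # indexed by stay_id, columns are descriptor names
    descriptors: list[FeatureDescriptor] = field(default_factory=list)

    @property
    def stay_ids(self) -> pd.Index:
        return self.df.index

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index_label="stay_id")

    def descriptor_json(self) -> list[dict]:
        return [
            {"variable_id": d.variable_id, "statistic": d.statistic, "window": d.window}
            for d in self.descriptors
        ]


# ---------------------------------------------------------------------------
# horizon assignment
# ---------------------------------------------------------------------------

def assign_horizon(
    events: pd.DataFrame,
    thresholds: tuple[float, float] = (2.0, 12.0),
    stay_col: str = "stay_id",
) -> str:
    """Assign high/medium/low horizon from the median sampling interval.

    Consecutive within-stay inter-measurement intervals are pooled across
    stays; their median (in hours) is compared to the two thresholds
    (default 2 h and 12 h).  Variables with fewer than two timestamps get
    horizon ``low``.
    """
    if len(events) < 2:
        return "low"
    ts = events.sort_values([stay_col, "timestamp"]) if stay_col in events else events.sort_values("timestamp")
    if stay_col in ts:
        deltas = ts.groupby(stay_col, sort=False)["timestamp"].diff().dropna()
    else:
        deltas = ts["timestamp"].diff().dropna()
    if deltas.empty:
        return "low"
    med_hours = deltas.median() / HOUR
    lo, hi = thresholds
    if med_hours <= lo:
        return "high"
    if med_hours <= hi:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# per-class descriptor enumeration
# ---------------------------------------------------------------------------

def descriptors_for(spec: VariableSpec, horizon: str | None = None) -> list[FeatureDescriptor]:
    """Deterministically ordered feature columns for one variable."""
    v = spec.variable_id
    if spec.var_class == "timeseries":
        h = horizon or (spec.horizon if spec.horizon != "auto" else "low")
        return [
            FeatureDescriptor(v, stat, w)
            for w in HORIZON_WINDOWS[h]
            for stat in TIMESERIES_STATS
        ]
    if spec.var_class == "flow":
        return [FeatureDescriptor(v, "extrapolated_flow", w) for w in FLOW_WINDOWS]
    if spec.var_class == "medication":
        return [
            FeatureDescriptor(v, stat, w)
            for w in MEDICATION_WINDOWS
            for stat in ("indicator", "unique_count")
        ]
    if spec.var_class == "intervention":
        return [FeatureDescriptor(v, "indicator", w) for w in INTERVENTION_WINDOWS] + [
            FeatureDescriptor(v, "days_since_last", "history"),
            FeatureDescriptor(v, "last_value", "history"),
        ]
    if spec.var_class == "static":
        return [FeatureDescriptor(v, "last_value", spec.static_interval)]
    raise FeaturizeError(f"unknown variable class {spec.var_class!r}")


# ---------------------------------------------------------------------------
# per-class featurizers (single stay)
# ---------------------------------------------------------------------------

def _window_mask(ts: np.ndarray, discharge: pd.Timestamp, window: str) -> np.ndarray:
    w = pd.Timedelta(hours=WINDOW_HOURS[window])
    return (ts > discharge - w) & (ts <= discharge)


def timeseries_features(
    events: pd.DataFrame, discharge_ts: pd.Timestamp, horizon: str
) -> dict[FeatureDescriptor, float]:
    """Median/IQR/min/max/trend over the horizon's three windows (15 values).

    Windows with no observation yield all-missing; a single observation
    leaves the trend missing (slope undefined) but defines the rest.
    """
    var = events["variable_id"].iloc[0] if len(events) else "?"
    vals_all = pd.to_numeric(events["value"], errors="coerce")
    if vals_all.isna().any() and len(events):
        raise FeaturizeError(f"non-numeric value for variable {var!r}")
    out: dict[FeatureDescriptor, float] = {}
    ts = events["timestamp"].to_numpy() if len(events) else np.array([], dtype="datetime64[ns]")
    vv = vals_all.to_numpy(dtype=float)
    for window in HORIZON_WINDOWS[horizon]:
        m = _window_mask(ts, discharge_ts, window) if len(events) else np.zeros(0, bool)
        v = vv[m]
        t = ts[m]
        stats: dict[str, float]
        if v.size == 0:
            stats = {s: np.nan for s in TIMESERIES_STATS}
        else:
            q25, q75 = np.quantile(v, [0.25, 0.75])
            stats = {
                "median": float(np.median(v)),
                "iqr": float(q75 - q25),
                "min": float(v.min()),
                "max": float(v.max()),
                "trend_per_day": _ols_slope_per_day(t, v),
            }
        for s in TIMESERIES_STATS:
            out[FeatureDescriptor(var, s, window)] = stats[s]
    return out


def _ols_slope_per_day(ts: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope in value units per day; NaN when undefined."""
    if values.size < 2:
        return np.nan
    t = (ts - ts.min()) / np.timedelta64(1, "D")
    t = np.asarray(t, dtype=float)
    vt = t.var()
    if vt == 0.0:
        return np.nan
    return float(np.cov(t, values, bias=True)[0, 1] / vt)


def flow_features(
    events: pd.DataFrame, discharge_ts: pd.Timestamp
) -> dict[FeatureDescriptor, float]:
    """Daily-rate extrapolation of recorded volumes over 1/3/7-day windows.

    ``sum(volumes in window) * 24h / window_hours``; an empty window counts
    as zero flow (no record means nothing was collected).
    """
    var = events["variable_id"].iloc[0] if len(events) else "?"
    vv = pd.to_numeric(events["value"], errors="coerce").to_numpy(dtype=float) if len(events) else np.zeros(0)
    if np.any(vv < 0):
        raise FeaturizeError(f"negative flow volume for variable {var!r}")
    ts = events["timestamp"].to_numpy() if len(events) else np.array([], dtype="datetime64[ns]")
    out = {}
    for window in FLOW_WINDOWS:
        m = _window_mask(ts, discharge_ts, window) if len(events) else np.zeros(0, bool)
        total = float(vv[m].sum())
        out[FeatureDescriptor(var, "extrapolated_flow", window)] = total * 24.0 / WINDOW_HOURS[window]
    return out


def medication_features(
    events: pd.DataFrame, discharge_ts: pd.Timestamp
) -> dict[FeatureDescriptor, float]:
    """Administration indicator and unique-drug count per 1/3/7-day window.

    The event ``value`` carries the drug identity within the medication
    category; distinct values are distinct drugs.
    """
    var = events["variable_id"].iloc[0] if len(events) else "?"
    ts = events["timestamp"].to_numpy() if len(events) else np.array([], dtype="datetime64[ns]")
    drug = events["value"].to_numpy() if len(events) else np.zeros(0)
    out = {}
    for window in MEDICATION_WINDOWS:
        m = _window_mask(ts, discharge_ts, window) if len(events) else np.zeros(0, bool)
        n_unique = len(set(drug[m].tolist()))
        out[FeatureDescriptor(var, "indicator", window)] = float(n_unique > 0)
        out[FeatureDescriptor(var, "unique_count", window)] = float(n_unique)
    return out


def intervention_features(
    events: pd.DataFrame, discharge_ts: pd.Timestamp
) -> dict[FeatureDescriptor, float]:
    """Indicator per 3/7-day window, days since last performed, last value.

    ``days_since_last`` is computed over the full pre-discharge history; an
    intervention never performed stays missing (rendered as the "unknown"
    bin by the model).
    """
    var = events["variable_id"].iloc[0] if len(events) else "?"
    ts = events["timestamp"].to_numpy() if len(events) else np.array([], dtype="datetime64[ns]")
    pre = ts[ts <= np.datetime64(discharge_ts)] if len(events) else ts
    out = {}
    for window in INTERVENTION_WINDOWS:
        m = _window_mask(ts, discharge_ts, window) if len(events) else np.zeros(0, bool)
        out[FeatureDescriptor(var, "indicator", window)] = float(m.any())
    if pre.size:
        last = pre.max()
        out[FeatureDescriptor(var, "days_since_last", "history")] = float(
            (np.datetime64(discharge_ts) - last) / np.timedelta64(1, "D")
        )
        idx = int(np.argmax(events["timestamp"].to_numpy() == last))
        out[FeatureDescriptor(var, "last_value", "history")] = float(
            pd.to_numeric(events["value"].iloc[idx], errors="coerce")
        )
    else:
        out[FeatureDescriptor(var, "days_since_last", "history")] = np.nan
        out[FeatureDescriptor(var, "last_value", "history")] = np.nan
    return out


def static_features(
    events: pd.DataFrame,
    discharge_ts: pd.Timestamp,
    interval_tag: str,
    interval_start: pd.Timestamp | None = None,
) -> dict[FeatureDescriptor, float]:
    """Last recorded value within the tagged interval (patient history,
    hospital stay, or ICU stay); missing when never recorded."""
    if interval_tag not in STATIC_INTERVALS:
        raise FeaturizeError(f"unknown static interval {interval_tag!r}")
    var = events["variable_id"].iloc[0] if len(events) else "?"
    d = FeatureDescriptor(var, "last_value", interval_tag)
    if not len(events):
        return {d: np.nan}
    ts = events["timestamp"]
    mask = ts <= discharge_ts
    if interval_start is not None:
        mask &= ts >= interval_start
    sub = events.loc[mask]
    if not len(sub):
        return {d: np.nan}
    row = sub.loc[sub["timestamp"].idxmax()]
    return {d: float(pd.to_numeric(row["value"], errors="coerce"))}


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def build_matrix(
    stays: pd.DataFrame,
    events: pd.DataFrame,
    variable_specs: Sequence[VariableSpec],
    transfers: pd.DataFrame | None = None,
    include_manual: bool = True,
    horizon_thresholds: tuple[float, float] = (2.0, 12.0),
) -> FeatureMatrix:
    """Assemble the stays x features matrix.

    ``stays`` needs columns stay_id, patient_id, admit_ts, discharge_ts.
    ``events`` is the long event log (stay_id, timestamp, variable_id,
    value).  Unknown variables in the event log (not covered by a spec)
    raise; unknown variable classes raise.  When ``include_manual`` is set
    and ``transfers`` is given, the manually curated feature
    ``length_of_stay_before_icu`` (days between first hospital contact and
    ICU admission) is appended.
    """
    specs = {s.variable_id: s for s in variable_specs}
    present = set(events["variable_id"].unique()) if len(events) else set()
    unknown = present - set(specs)
    if unknown:
        raise FeaturizeError(f"variables without spec: {sorted(unknown)}")

    stays = stays.reset_index(drop=True)
    # resolve horizons once per variable
    horizons: dict[str, str] = {}
    for vid, spec in specs.items():
        if spec.var_class != "timeseries":
            horizons[vid] = "low"
        elif spec.horizon != "auto":
            horizons[vid] = spec.horizon
        else:
            ev = events.loc[events["variable_id"] == vid] if len(events) else events
            horizons[vid] = assign_horizon(ev, horizon_thresholds)

    descriptors: list[FeatureDescriptor] = []
    for vid in sorted(specs):
        descriptors.extend(descriptors_for(specs[vid], horizons[vid]))
    if include_manual:
        descriptors.append(FeatureDescriptor(MANUAL_LOS_FEATURE, "manual", "hospital_stay"))

    cols = [d.name for d in descriptors]
    n = len(stays)
    data = np.full((n, len(cols)), np.nan)
    col_idx = {c: j for j, c in enumerate(cols)}

    ev = events.loc[events["stay_id"].isin(set(stays["stay_id"]))] if len(events) else events
    grouped: dict[tuple, pd.DataFrame] = (
        {k: g for k, g in ev.groupby(["stay_id", "variable_id"], sort=False)} if len(ev) else {}
    )

    for i, stay in stays.iterrows():
        sid, discharge = stay["stay_id"], stay["discharge_ts"]
        admit = stay["admit_ts"]
        for vid, spec in specs.items():
            g = grouped.get((sid, vid))
            g = g if g is not None else ev.iloc[0:0]
            if len(g):
                g = g.loc[g["timestamp"] <= discharge]
            if not len(g):
                vals = _empty_values(spec, horizons[vid])
            elif spec.var_class == "timeseries":
                vals = timeseries_features(_with_var(g, vid), discharge, horizons[vid])
            elif spec.var_class == "flow":
                vals = flow_features(_with_var(g, vid), discharge)
            elif spec.var_class == "medication":
                vals = medication_features(_with_var(g, vid), discharge)
            elif spec.var_class == "intervention":
                vals = intervention_features(_with_var(g, vid), discharge)
            else:  # static
                start = admit if spec.static_interval == "icu_stay" else None
                vals = static_features(_with_var(g, vid), discharge, spec.static_interval, start)
            for d, x in vals.items():
                data[i, col_idx[d.name]] = x
        if include_manual and transfers is not None:
            pt = transfers.loc[transfers["patient_id"] == stay["patient_id"]]
            pre = pt.loc[pt["admit_ts"] <= admit]
            if len(pre):
                first = pre["admit_ts"].min()
                data[i, col_idx[descriptors[-1].name]] = float((admit - first) / DAY)

    df = pd.DataFrame(data, index=pd.Index(stays["stay_id"], name="stay_id"), columns=cols)
    return FeatureMatrix(df=df, descriptors=descriptors)


def _empty_values(spec: VariableSpec, horizon: str) -> dict[FeatureDescriptor, float]:
    """Feature values for a stay with no events of this variable.

    Time series and statics stay missing; flows count as zero collection;
    medications were not administered; interventions were never performed
    (indicator 0, interval missing).
    """
    vid = spec.variable_id
    if spec.var_class == "timeseries":
        return {d: np.nan for d in descriptors_for(spec, horizon)}
    if spec.var_class == "flow":
        return {FeatureDescriptor(vid, "extrapolated_flow", w): 0.0 for w in FLOW_WINDOWS}
    if spec.var_class == "medication":
        vals: dict[FeatureDescriptor, float] = {}
        for w in MEDICATION_WINDOWS:
            vals[FeatureDescriptor(vid, "indicator", w)] = 0.0
            vals[FeatureDescriptor(vid, "unique_count", w)] = 0.0
        return vals
    if spec.var_class == "intervention":
        vals = {FeatureDescriptor(vid, "indicator", w): 0.0 for w in INTERVENTION_WINDOWS}
        vals[FeatureDescriptor(vid, "days_since_last", "history")] = np.nan
        vals[FeatureDescriptor(vid, "last_value", "history")] = np.nan
        return vals
    return {FeatureDescriptor(vid, "last_value", spec.static_interval): np.nan}


def _with_var(g: pd.DataFrame, vid: str) -> pd.DataFrame:
    if len(g) and g["variable_id"].iloc[0] == vid:
        return g
    g = g.copy()
    g["variable_id"] = vid
    return g
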