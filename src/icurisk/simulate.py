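"""Synthetic ICU cohort generator with known additive outcome structure.

Emulates the raw material of an ICU readmission study: a transfer table
(unit admissions/discharges with dispositions) and a long event log of
routinely collected variables spanning the five featurizable classes, with
per-variable Poisson-like sampling cadences (exponential inter-arrival
times; roughly 15 min for high-, 6 h for medium- and 1 day for low-horizon
variables).  The 3-day readmission/death outcome is drawn from a known
additive model: a Bernoulli label whose logit is an intercept plus a sum of
piecewise-constant truth terms evaluated on engineered features of the
stay, with the intercept solved by 1-D root finding so the mean event
probability hits a configured prevalence (about 5-9% by default).  The
label is drawn first and a consistent readmission or death transfer is then
materialised, so cohort labelling can be tested against stored truth.

A dataset-shift artifact can be injected: values of one variable are
transformed from a calendar date onward (emulating a measurement-procedure
change in a late study year) *after* outcomes are drawn, so the shift
corrupts the measured feature but not the underlying risk.

Two entry points:

* :func:`generate_cohort` — full event-level generation (transfer table +
  event log + truth), exercising merging, labelling and featurization.
* :func:`sample_feature_matrix` — draws engineered features directly with
  the same truth-term representation, for model-level experiments at large
  n where the event layer adds nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit as _logit_fn

from .features import (
    DAY,
    FeatureDescriptor,
    VariableSpec,
    build_matrix,
)

__all__ = [
    "VariableSim",
    "TruthTerm",
    "ArtifactSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_cohort",
    "inject_artifact",
    "oracle_logit",
    "sample_feature_matrix",
    "default_config",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class VariableSim:
    """Generator-side description of one variable.

    ``cadence_hours`` is the mean exponential inter-arrival time of
    measurements; ``mean``/``sd`` the within-stay Gaussian value
    distribution, and ``between_sd`` the SD of the per-stay mean shift
    (this is what gives window statistics between-stay signal).
    """

    variable_id: str
    var_class: str  # timeseries | flow | medication | intervention | static
    cadence_hours: float = 24.0
    mean: float = 0.0
    sd: float = 1.0
    between_sd: float = 1.0
    presence_prob: float = 1.0  # probability the stay has this variable at all
    n_drugs: int = 5  # medication class: distinct drug identities

    def __post_init__(self) -> None:
        if self.cadence_hours <= 0:
            raise SimulationError(f"cadence must be positive for {self.variable_id!r}")


@dataclass(frozen=True)
class TruthTerm:
    """A known piecewise-constant risk function on one engineered feature."""

    feature: FeatureDescriptor
    cuts: tuple[float, ...]
    scores: tuple[float, ...]  # len(cuts) + 1 finite-bin scores
    missing_score: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.cuts) + 1:
            raise SimulationError("need len(cuts)+1 scores")
        if list(self.cuts) != sorted(self.cuts):
            raise SimulationError("cuts must be increasing")

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        """Per-row log-odds contribution; NaN maps to the missing score."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts), v, side="left")
        out = np.asarray(self.scores, dtype=float)[np.clip(idx, 0, len(self.scores) - 1)]
        out = np.where(np.isnan(v), self.missing_score, out)
        return self.weight * out


@dataclass(frozen=True)
class ArtifactSpec:
    """A calendar-dated value transform: v -> v * scale + offset from
    ``shift_date`` onward (emulating a measurement-procedure change)."""

    variable_id: str
    shift_date: pd.Timestamp
    scale: float = 1.0
    offset: float = 0.0


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 4000
    year_start: int = 2012
    year_end: int = 2019
    prevalence_target: float = 0.057
    intercept_true: float | None = None  # overrides the prevalence solve
    variables: list[VariableSim] = field(default_factory=lambda: default_variables())
    truth_terms: list[TruthTerm] = field(default_factory=lambda: default_truth_terms())
    artifact_specs: list[ArtifactSpec] = field(default_factory=lambda: default_artifacts())
    los_mean_days: float = 3.7
    los_sigma: float = 0.9  # lognormal shape
    frac_split_transfers: float = 0.15
    frac_death_at_discharge: float = 0.08
    frac_external: float = 0.08
    cause_probs: tuple[float, float, float] = (822 / 891, 31 / 891, 38 / 891)
    late_readmit_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise SimulationError("prevalence_target must be in (0, 1)")
        if self.year_end <= self.year_start:
            raise SimulationError("year_range must span at least two years")
        known = {v.variable_id for v in self.variables}
        for t in self.truth_terms:
            if t.feature.variable_id not in known:
                raise SimulationError(
                    f"truth term references unknown variable {t.feature.variable_id!r}"
                )


def default_variables() -> list[VariableSim]:
    return [
        VariableSim("heart_rate", "timeseries", cadence_hours=0.25, mean=85, sd=6, between_sd=13),
        VariableSim("ptt", "timeseries", cadence_hours=6.0, mean=40, sd=3, between_sd=8),
        VariableSim("creatinine", "timeseries", cadence_hours=24.0, mean=1.1, sd=0.15, between_sd=0.5),
        VariableSim("temperature", "timeseries", cadence_hours=4.0, mean=37.0, sd=0.3, between_sd=0.4),
        VariableSim("urine_output", "flow", cadence_hours=4.0, mean=1500, sd=0.25, between_sd=0.45),
        VariableSim("antithrombotics", "medication", cadence_hours=12.0, presence_prob=0.7, n_drugs=4),
        VariableSim("endotracheal_tube", "intervention", cadence_hours=24.0, presence_prob=0.55),
        VariableSim("age", "static", mean=63.3, sd=14.7),
    ]


def default_truth_terms() -> list[TruthTerm]:
    return [
        TruthTerm(FeatureDescriptor("age", "last_value", "patient"),
                  cuts=(50.0, 65.0, 78.0), scores=(-0.6, -0.15, 0.25, 0.7)),
        TruthTerm(FeatureDescriptor("heart_rate", "median", "24h"),
                  cuts=(70.0, 90.0, 108.0), scores=(0.2, -0.35, 0.1, 0.8)),
        TruthTerm(FeatureDescriptor("endotracheal_tube", "days_since_last", "history"),
                  cuts=(1.0, 3.0), scores=(0.9, 0.2, -0.25), missing_score=0.3),
        TruthTerm(FeatureDescriptor("ptt", "median", "24h"),
                  cuts=(35.0, 47.0), scores=(-0.3, 0.0, 0.6)),
        TruthTerm(FeatureDescriptor("urine_output", "extrapolated_flow", "1d"),
                  cuts=(600.0, 1600.0), scores=(0.7, 0.0, -0.3)),
    ]


def default_artifacts() -> list[ArtifactSpec]:
    return [ArtifactSpec("ptt", pd.Timestamp("2019-01-01"), scale=1.0, offset=15.0)]


def variable_specs_for(config: SimConfig) -> list[VariableSpec]:
    """Featurizer-side specs matching the generator's variables."""
    specs = []
    for v in config.variables:
        if v.var_class == "static":
            specs.append(VariableSpec(v.variable_id, "static", static_interval="patient"))
        else:
            specs.append(VariableSpec(v.variable_id, v.var_class, horizon="auto"))
    return specs


@dataclass
class SyntheticTruth:
    """Stored ground truth of one generated cohort."""

    stays: pd.DataFrame  # stay_id, patient_id, admit_ts, discharge_ts, true_logit, prob, label, cause
    truth_terms: list[TruthTerm]
    intercept_true: float
    artifact_ledger: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "intercept_true": self.intercept_true,
            "truth_terms": [
                {
                    "feature": t.feature.name,
                    "cuts": list(t.cuts),
                    "scores": list(t.scores),
                    "missing_score": t.missing_score,
                    "weight": t.weight,
                }
                for t in self.truth_terms
            ],
            "artifact_ledger": self.artifact_ledger,
            "stays": self.stays.assign(
                admit_ts=self.stays["admit_ts"].astype(str),
                discharge_ts=self.stays["discharge_ts"].astype(str),
            ).to_dict(orient="list"),
        }
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def oracle_logit(features_row, truth: SyntheticTruth) -> float:
    """True log-odds of a single stay given its engineered features.

    ``features_row`` maps feature names to values; a missing (absent or
    NaN) feature contributes the term's missing score.
    """
    total = truth.intercept_true
    for t in truth.truth_terms:
        v = features_row.get(t.feature.name, np.nan)
        total += float(t.evaluate(np.array([v]))[0])
    return float(total)


def _solve_intercept(raw: np.ndarray, prevalence: float) -> float:
    """Root-find beta0 so mean(expit(beta0 + raw)) == prevalence."""

    def f(c: float) -> float:
        return float(expit(c + raw).mean() - prevalence)

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise SimulationError("prevalence target unattainable for the given truth terms")
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifact(events: pd.DataFrame, spec: ArtifactSpec) -> pd.DataFrame:
    """Transform one variable's values at/after the shift date.

    Returns a new event table; rows before the shift date are untouched.
    """
    if spec.variable_id not in set(events["variable_id"].unique()):
        raise SimulationError(f"unknown variable {spec.variable_id!r} in artifact spec")
    out = events.copy()
    mask = (out["variable_id"] == spec.variable_id) & (out["timestamp"] >= spec.shift_date)
    out.loc[mask, "value"] = out.loc[mask, "value"] * spec.scale + spec.offset
    return out


# ---------------------------------------------------------------------------
# event-level generation
# ---------------------------------------------------------------------------

def _sample_event_times(rng, admit, discharge, cadence_hours) -> np.ndarray:
    los_h = (discharge - admit) / pd.Timedelta(hours=1)
    n_max = int(los_h / cadence_hours * 3 + 10)
    gaps = rng.exponential(cadence_hours, size=n_max)
    t = np.cumsum(gaps)
    t = t[t < los_h]
    return admit + pd.to_timedelta(t, unit="h")


def generate_cohort(config: SimConfig, seed: int | None = None):
    """Generate (transfer table, event log, SyntheticTruth).

    Deterministic given the seed.  Outcomes exist only for *eligible* index
    stays (those surviving the death/external/follow-up exclusions); every
    positive stay gets a consistent ICU/IMC readmission or death transfer
    within 3 days of discharge.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    study_start = pd.Timestamp(f"{config.year_start}-01-01")
    study_end = pd.Timestamp(f"{config.year_end}-12-31")
    span_days = (study_end - study_start) / DAY

    # --- index stays ------------------------------------------------------
    admit_offset = rng.uniform(0, span_days - 0.5, size=n)
    mu = np.log(config.los_mean_days) - config.los_sigma**2 / 2
    los = np.maximum(rng.lognormal(mu, config.los_sigma, size=n), 0.25)
    admits = study_start + pd.to_timedelta(np.round(admit_offset * 86400), unit="s")
    discharges = admits + pd.to_timedelta(np.round(los * 86400), unit="s")
    cap = study_end - pd.Timedelta(hours=1)
    discharges = pd.DatetimeIndex(np.minimum(discharges.to_numpy(), np.datetime64(cap)))

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    stay_ids = np.array([f"S{i:06d}" for i in range(n)])

    u = rng.uniform(size=n)
    disposition = np.where(
        u < config.frac_death_at_discharge, "death",
        np.where(u < config.frac_death_at_discharge + config.frac_external, "external", "standard_care"),
    )
    followup_ok = discharges + 3 * DAY <= study_end
    eligible = (disposition == "standard_care") & followup_ok

    stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "patient_id": patient_ids,
            "admit_ts": admits,
            "discharge_ts": discharges,
            "disposition": disposition,
            "eligible": eligible,
        }
    )

    # --- events -----------------------------------------------------------
    ev_rows: list[pd.DataFrame] = []
    for v in config.variables:
        present = rng.uniform(size=n) < v.presence_prob
        if v.var_class == "static":
            mask = present
            vals = np.clip(rng.normal(v.mean, v.sd, size=n), 18, 99)
            ev_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids[mask],
                        "stay_id": stay_ids[mask],
                        "timestamp": admits[mask],
                        "variable_id": v.variable_id,
                        "value": np.round(vals[mask], 1),
                        "variable_class": v.var_class,
                    }
                )
            )
            continue
        stay_mean = rng.normal(v.mean, v.between_sd, size=n)
        daily_rate = None
        if v.var_class == "flow":
            daily_rate = np.exp(rng.normal(np.log(v.mean), v.between_sd, size=n))
        ts_parts: list[np.ndarray] = []
        val_parts: list[np.ndarray] = []
        sid_parts: list[np.ndarray] = []
        pid_parts: list[np.ndarray] = []
        for i in range(n):
            if not present[i]:
                continue
            if v.var_class == "intervention":
                # device present from admission until a stay-specific stop time
                stop_back = rng.exponential(1.5)  # days before discharge it stopped
                last = max(admits[i], discharges[i] - pd.Timedelta(days=stop_back))
                times = pd.date_range(admits[i], last, freq="24h")
                if len(times) == 0 or times[-1] < last:
                    times = times.append(pd.DatetimeIndex([last]))
                times = times.to_numpy()
                vals = np.ones(len(times))
            else:
                times = _sample_event_times(rng, admits[i], discharges[i], v.cadence_hours)
                if len(times) == 0:
                    continue
                times = np.asarray(times.values if hasattr(times, "values") else times)
                if v.var_class == "medication":
                    vals = rng.integers(1, v.n_drugs + 1, size=len(times)).astype(float)
                elif v.var_class == "flow":
                    per_event = daily_rate[i] * v.cadence_hours / 24.0
                    vals = np.round(np.maximum(rng.normal(per_event, per_event * v.sd, size=len(times)), 0.0), 1)
                else:
                    vals = np.round(rng.normal(stay_mean[i], v.sd, size=len(times)), 2)
            ts_parts.append(times)
            val_parts.append(vals)
            sid_parts.append(np.repeat(stay_ids[i], len(times)))
            pid_parts.append(np.repeat(patient_ids[i], len(times)))
        if ts_parts:
            ev_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": np.concatenate(pid_parts),
                        "stay_id": np.concatenate(sid_parts),
                        "timestamp": pd.DatetimeIndex(np.concatenate(ts_parts)),
                        "variable_id": v.variable_id,
                        "value": np.concatenate(val_parts),
                        "variable_class": v.var_class,
                    }
                )
            )
    events = pd.concat(ev_rows, ignore_index=True)
    events = events.sort_values(["stay_id", "variable_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    # --- truth and outcomes ----------------------------------------------
    truth_vars = {t.feature.variable_id for t in config.truth_terms}
    specs = [s for s in variable_specs_for(config) if s.variable_id in truth_vars]
    elig = stays.loc[stays["eligible"]].reset_index(drop=True)
    fm = build_matrix(
        elig[["stay_id", "patient_id", "admit_ts", "discharge_ts"]],
        events.loc[events["stay_id"].isin(set(elig["stay_id"])) & events["variable_id"].isin(truth_vars)],
        specs,
        include_manual=False,
    )
    raw = np.zeros(len(elig))
    for t in config.truth_terms:
        col = t.feature.name
        vals = fm.df[col].to_numpy() if col in fm.df.columns else np.full(len(elig), np.nan)
        raw += t.evaluate(vals)
    if config.intercept_true is not None:
        beta0 = float(config.intercept_true)
    elif config.truth_terms:
        beta0 = _solve_intercept(raw, config.prevalence_target)
    else:
        beta0 = float(_logit_fn(config.prevalence_target))
    probs = expit(beta0 + raw)
    labels = (rng.uniform(size=len(elig)) < probs).astype(int)
    causes = np.where(labels == 1, "", "none").astype(object)
    cp = np.asarray(config.cause_probs, dtype=float)
    cp = cp / cp.sum()
    for k in np.flatnonzero(labels == 1):
        causes[k] = rng.choice(["icu_readmit", "imc_readmit", "death"], p=cp)

    # --- transfer table ---------------------------------------------------
    rows = []
    split = rng.uniform(size=n) < config.frac_split_transfers
    ward_before = rng.uniform(size=n) < 0.4  # admitted via a normal ward first
    ward_days = rng.uniform(0.5, 6.0, size=n)
    for i in range(n):
        hosp = f"H{i:06d}"
        if ward_before[i]:
            w_admit = admits[i] - pd.Timedelta(seconds=round(ward_days[i] * 86400))
            rows.append((patient_ids[i], hosp, "WARD-0", "WARD", w_admit, admits[i],
                         "standard_care"))
        if split[i] and (discharges[i] - admits[i]) > pd.Timedelta(hours=6):
            mid = admits[i] + (discharges[i] - admits[i]) / 2
            gap = pd.Timedelta(minutes=int(rng.integers(5, 45)))
            rows.append((patient_ids[i], hosp, "ICU-1", "ICU", admits[i], mid, "standard_care"))
            rows.append((patient_ids[i], hosp, "ICU-2", "ICU", mid + gap, discharges[i], disposition[i]))
        else:
            unit = f"ICU-{int(rng.integers(1, 5))}"
            rows.append((patient_ids[i], hosp, unit, "ICU", admits[i], discharges[i], disposition[i]))

    elig_index = {sid: k for k, sid in enumerate(elig["stay_id"])}
    for i in range(n):
        sid = stay_ids[i]
        k = elig_index.get(sid)
        hosp = f"H{i:06d}"
        if k is None:
            continue
        if labels[k] == 1:
            cause = causes[k]
            delay_h = rng.uniform(2.0, 72.0)
            ev_ts = discharges[i] + pd.Timedelta(seconds=round(delay_h * 3600))
            ev_ts = min(ev_ts, discharges[i] + 3 * DAY)
            if cause == "death":
                rows.append((patient_ids[i], hosp, "WARD-1", "WARD", discharges[i], ev_ts, "death"))
            else:
                unit_type = "ICU" if cause == "icu_readmit" else "IMC"
                unit = f"{unit_type}-R"
                stay_len = pd.Timedelta(days=float(rng.uniform(1, 4)))
                rows.append((patient_ids[i], hosp, unit, unit_type, ev_ts, ev_ts + stay_len, "standard_care"))
            causes[k] = cause
        elif rng.uniform() < config.late_readmit_frac:
            ev_ts = discharges[i] + pd.Timedelta(days=float(rng.uniform(3.5, 10.0)))
            rows.append((patient_ids[i], hosp, "ICU-L", "ICU", ev_ts, ev_ts + pd.Timedelta(days=2), "standard_care"))

    transfers = pd.DataFrame(
        rows,
        columns=["patient_id", "hospital_stay_id", "unit_id", "unit_type", "admit_ts", "discharge_ts", "disposition"],
    ).sort_values(["patient_id", "admit_ts"], kind="mergesort").reset_index(drop=True)

    truth_stays = elig[["stay_id", "patient_id", "admit_ts", "discharge_ts"]].copy()
    truth_stays["true_logit"] = beta0 + raw
    truth_stays["prob"] = probs
    truth_stays["label"] = labels
    truth_stays["cause"] = causes
    truth = SyntheticTruth(
        stays=truth_stays,
        truth_terms=list(config.truth_terms),
        intercept_true=beta0,
        artifact_ledger=[],
    )

    # --- artifacts (post-outcome: corrupt measurements, not risk) ---------
    for spec in config.artifact_specs:
        if spec.variable_id not in set(events["variable_id"].unique()):
            raise SimulationError(f"artifact references unknown variable {spec.variable_id!r}")
        events = inject_artifact(events, spec)
        truth.artifact_ledger.append(
            {
                "variable_id": spec.variable_id,
                "shift_date": str(spec.shift_date),
                "scale": spec.scale,
                "offset": spec.offset,
            }
        )

    return transfers, events, truth


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


# ---------------------------------------------------------------------------
# direct feature-matrix sampling
# ---------------------------------------------------------------------------

def _template_terms(n_signal: int, strength: float) -> list[TruthTerm]:
    """Deterministic piecewise shapes on standard-normal features."""
    cuts = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)
    # piecewise approximations of smooth monotone / U / hump risk curves,
    # all levels distinct
    shapes = [
        (cuts, (-1.2, -0.9, -0.5, -0.1, 0.3, 0.7, 1.0, 1.2)),
        (cuts, (1.1, 0.6, 0.15, -0.25, -0.45, -0.2, 0.3, 0.9)),
        (cuts, (1.2, 0.8, 0.45, 0.1, -0.2, -0.5, -0.8, -1.1)),
        (cuts, (-0.9, -0.3, 0.2, 0.7, 0.9, 0.5, 0.0, -0.6)),
        (cuts, (-1.0, -0.7, -0.35, -0.05, 0.25, 0.5, 0.85, 1.15)),
    ]
    terms = []
    for i in range(n_signal):
        cuts, scores = shapes[i % len(shapes)]
        terms.append(
            TruthTerm(
                FeatureDescriptor(f"x{i:02d}", "value", "sim"),
                cuts=cuts,
                scores=tuple(strength * s for s in scores),
            )
        )
    return terms


def sample_feature_matrix(
    n: int,
    n_signal: int = 5,
    n_null: int = 20,
    prevalence: float = 0.06,
    seed: int = 0,
    year_range: tuple[int, int] = (2012, 2019),
    signal_strength: float = 1.0,
    truth_terms: list[TruthTerm] | None = None,
):
    """Draw an engineered feature matrix directly from known truth terms.

    Returns ``(X, y, years, truth)`` where ``X`` holds standard-normal
    signal features (named per the truth terms) plus ``n_null`` pure-noise
    features, ``years`` is a uniform calendar-year column for temporal
    splitting, and ``truth`` stores per-row logits and the terms.
    """
    rng = np.random.default_rng(seed)
    terms = truth_terms if truth_terms is not None else _template_terms(n_signal, signal_strength)
    cols = {}
    raw = np.zeros(n)
    for t in terms:
        v = rng.normal(size=n)
        cols[t.feature.name] = v
        raw += t.evaluate(v)
    for j in range(n_null):
        cols[f"null{j:02d}"] = rng.normal(size=n)
    X = pd.DataFrame(cols)
    beta0 = _solve_intercept(raw, prevalence)
    probs = expit(beta0 + raw)
    y = (rng.uniform(size=n) < probs).astype(int)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    truth = SyntheticTruth(
        stays=pd.DataFrame(
            {
                "stay_id": [f"S{i:06d}" for i in range(n)],
                "true_logit": beta0 + raw,
                "prob": probs,
                "label": y,
            }
        ),
        truth_terms=list(terms),
        intercept_true=beta0,
    )
    return X, y, years, truth
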