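"""Cohort assembly: from raw unit transfers to labelled ICU stays.

Three stages, mirroring a retrospective readmission-study pipeline:

1. :func:`merge_transfers` — consecutive ICU transfers of a patient with a
   short administrative gap (default 1 h) are one ICU stay; larger gaps
   start a new stay (and hence count as readmissions downstream).
2. :func:`apply_exclusions` — stays ending in death, discharged to an
   external ICU/IMC, or lacking a full 3-day follow-up window before the
   study end are removed, with a per-reason tally (first matching reason
   wins, in that fixed order).
3. :func:`label_stays` — a stay is positive iff the earliest qualifying
   event (readmission to any ICU or IMC unit, or death) falls within the
   follow-up interval (default 3 days, right-closed) of its discharge.

All operations are deterministic and invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

DAY = pd.Timedelta(days=1)

EXCLUSION_ORDER = ("death", "external", "insufficient_follow_up")
CAUSE_PRIORITY = {"icu_readmit": 0, "imc_readmit": 1, "death": 2}


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeLabel:
    positive: bool
    cause: str  # icu_readmit | imc_readmit | death | none
    event_ts: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.positive != (self.cause != "none"):
            raise CohortError("positive label must coincide with a non-none cause")


REQUIRED_TRANSFER_COLS = [
    "patient_id",
    "hospital_stay_id",
    "unit_id",
    "unit_type",
    "admit_ts",
    "discharge_ts",
    "disposition",
]


def read_transfers(path: str) -> pd.DataFrame:
    """Read the transfer CSV dialect (ISO-8601 timestamps)."""
    df = pd.read_csv(path, parse_dates=["admit_ts", "discharge_ts"])
    missing = [c for c in REQUIRED_TRANSFER_COLS if c not in df.columns]
    if missing:
        raise CohortError(f"transfer table lacks columns: {missing}")
    return df


def read_events(path: str) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_transfers(
    transfers: pd.DataFrame,
    gap_threshold: pd.Timedelta = pd.Timedelta(hours=1),
) -> pd.DataFrame:
    """Merge consecutive ICU transfers into ICU stays.

    Only ``unit_type == "ICU"`` rows form stays.  Per patient, transfers
    are sorted by admission; a transfer whose admission is within
    ``gap_threshold`` of the previous discharge continues the same stay.
    Overlapping transfers of one patient are rejected with their row ids.

    Returns a stays DataFrame (stay_id, patient_id, admit_ts,
    discharge_ts, disposition, source_transfers, n_transfers).
    """
    icu = transfers.loc[transfers["unit_type"] == "ICU"].copy()
    icu["row_id"] = icu.index
    bad = icu.loc[icu["admit_ts"] >= icu["discharge_ts"], "row_id"].tolist()
    if bad:
        raise CohortError(f"transfers with non-positive duration: {bad}")
    icu = icu.sort_values(["patient_id", "admit_ts", "discharge_ts"], kind="mergesort")

    stays = []
    for pid, grp in icu.groupby("patient_id", sort=True):
        cur: dict | None = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.admit_ts < cur["discharge_ts"]:
                raise CohortError(
                    f"overlapping transfers for patient {pid!r}: rows "
                    f"{cur['source_transfers'][-1]} and {row.row_id}"
                )
            if cur is not None and (row.admit_ts - cur["discharge_ts"]) <= gap_threshold:
                cur["discharge_ts"] = max(cur["discharge_ts"], row.discharge_ts)
                cur["disposition"] = row.disposition
                cur["source_transfers"].append(row.row_id)
                cur["n_transfers"] += 1
            else:
                if cur is not None:
                    stays.append(cur)
                cur = {
                    "patient_id": pid,
                    "admit_ts": row.admit_ts,
                    "discharge_ts": row.discharge_ts,
                    "disposition": row.disposition,
                    "source_transfers": [row.row_id],
                    "n_transfers": 1,
                }
        if cur is not None:
            stays.append(cur)

    out = pd.DataFrame(stays)
    if out.empty:
        return pd.DataFrame(
            columns=["stay_id", "patient_id", "admit_ts", "discharge_ts",
                     "disposition", "source_transfers", "n_transfers"]
        )
    out = out.sort_values(["patient_id", "admit_ts"], kind="mergesort").reset_index(drop=True)
    seq = out.groupby("patient_id", sort=False).cumcount()
    out.insert(0, "stay_id", out["patient_id"].astype(str) + "-" + seq.astype(str))
    return out


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    stays: pd.DataFrame,
    study_end_ts: pd.Timestamp,
    followup: pd.Timedelta = 3 * DAY,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop stays ending in death, external discharge, or without a full
    follow-up window; tally one reason per stay in cascade order."""
    tally = {r: 0 for r in EXCLUSION_ORDER}
    reasons = pd.Series("", index=stays.index, dtype=object)
    death = stays["disposition"] == "death"
    reasons[death] = "death"
    external = (stays["disposition"] == "external") & (reasons == "")
    reasons[external] = "external"
    short = (stays["discharge_ts"] + followup > study_end_ts) & (reasons == "")
    reasons[short] = "insufficient_follow_up"
    for r in EXCLUSION_ORDER:
        tally[r] = int((reasons == r).sum())
    kept = stays.loc[reasons == ""].reset_index(drop=True)
    return kept, tally


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def label_stays(
    stays: pd.DataFrame,
    transfers: pd.DataFrame,
    deaths: pd.DataFrame | None = None,
    interval: pd.Timedelta = 3 * DAY,
) -> pd.DataFrame:
    """Attach the 3-day readmission/death outcome to each stay.

    Qualifying events after a stay's discharge: admission to any ICU or
    IMC unit, or death.  Deaths come from an optional ``deaths`` table
    (patient_id, death_ts) and from transfer rows with disposition
    ``death`` (death time = that transfer's discharge).  The interval is
    right-closed: an event at exactly ``discharge + interval`` counts.
    Simultaneous events resolve by ICU > IMC > death priority.

    A death recorded at or before a stay's admission is a data error.
    """
    stays = stays.reset_index(drop=True)
    cand = transfers.loc[transfers["unit_type"].isin(["ICU", "IMC"])]

    death_rows = []
    dt = transfers.loc[transfers["disposition"] == "death"]
    for row in dt.itertuples(index=False):
        death_rows.append((row.patient_id, row.discharge_ts))
    if deaths is not None:
        for row in deaths.itertuples(index=False):
            death_rows.append((row.patient_id, row.death_ts))
    death_df = pd.DataFrame(death_rows, columns=["patient_id", "death_ts"])
    death_by_pid = {pid: g["death_ts"].min() for pid, g in death_df.groupby("patient_id")}

    adm_by_pid = {pid: g for pid, g in cand.groupby("patient_id")}

    labels, causes, event_ts = [], [], []
    for row in stays.itertuples(index=False):
        discharge = row.discharge_ts
        events: list[tuple[pd.Timestamp, int, str]] = []
        g = adm_by_pid.get(row.patient_id)
        if g is not None:
            after = g.loc[(g["admit_ts"] > discharge) & (g["admit_ts"] <= discharge + interval)]
            for r in after.itertuples(index=False):
                cause = "icu_readmit" if r.unit_type == "ICU" else "imc_readmit"
                events.append((r.admit_ts, CAUSE_PRIORITY[cause], cause))
        d = death_by_pid.get(row.patient_id)
        if d is not None:
            if d <= row.admit_ts:
                raise CohortError(
                    f"death at {d} precedes admission of stay {getattr(row, 'stay_id', '?')}"
                )
            if discharge < d <= discharge + interval:
                events.append((d, CAUSE_PRIORITY["death"], "death"))
        if events:
            ts, _, cause = min(events)
            labels.append(1)
            causes.append(cause)
            event_ts.append(ts)
        else:
            labels.append(0)
            causes.append("none")
            event_ts.append(pd.NaT)

    out = stays.copy()
    out["label"] = labels
    out["cause"] = causes
    out["event_ts"] = event_ts
    return out


def assemble_cohort(
    transfers: pd.DataFrame,
    study_end_ts: pd.Timestamp,
    gap_threshold: pd.Timedelta = pd.Timedelta(hours=1),
    interval: pd.Timedelta = 3 * DAY,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge, exclude and label in one call; returns (labelled stays, tally)."""
    stays = merge_transfers(transfers, gap_threshold)
    kept, tally = apply_exclusions(stays, study_end_ts, followup=interval)
    labelled = label_stays(kept, transfers, interval=interval)
    return labelled, tally
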