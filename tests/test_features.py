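"""Featurization against brute-force windowed-statistics oracles."""

import numpy as np
import pandas as pd
import pytest

import icurisk as ir
from icurisk.features import (
    FeaturizeError,
    HORIZON_WINDOWS,
    MANUAL_LOS_FEATURE,
    VariableSpec,
    assign_horizon,
    build_matrix,
    descriptors_for,
    flow_features,
    intervention_features,
    medication_features,
    static_features,
    timeseries_features,
)

import oracles

D = pd.Timedelta(days=1)
H = pd.Timedelta(hours=1)
T0 = pd.Timestamp("2016-03-01")


def ev_frame(var, times, values, stay="s0", pid="p0", vclass="timeseries"):
    return pd.DataFrame({
        "patient_id": pid, "stay_id": stay, "timestamp": list(times),
        "variable_id": var, "value": list(values), "variable_class": vclass,
    })


class TestAssignHorizon:
    def test_one_minute_cadence_is_high(self):
        times = pd.date_range(T0, periods=100, freq="1min")
        ev = ev_frame("hr", times, np.ones(100))
        assert assign_horizon(ev) == "high"

    def test_fewer_than_two_timestamps_low(self):
        ev = ev_frame("x", [T0], [1.0])
        assert assign_horizon(ev) == "low"

    @pytest.mark.parametrize("hours,expected", [(0.5, "high"), (2.0, "high"), (6.0, "medium"), (12.0, "medium"), (25.0, "low")])
    def test_threshold_rule(self, hours, expected):
        times = [T0 + i * pd.Timedelta(hours=hours) for i in range(20)]
        ev = ev_frame("x", times, np.ones(20))
        assert assign_horizon(ev) == expected

    def test_random_cadences_match_median_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            gaps = rng.exponential(rng.uniform(0.2, 30), size=n)
            times = [T0]
            for g in gaps:
                times.append(times[-1] + pd.Timedelta(hours=float(g)))
            ev = ev_frame("x", times, np.ones(len(times)))
            med = float(np.median(gaps))
            expected = "high" if med <= 2 else ("medium" if med <= 12 else "low")
            assert assign_horizon(ev) == expected

    def test_medication_always_low_in_matrix(self):
        # a medication sampled every minute must still use low windows
        times = pd.date_range(T0, periods=50, freq="1min")
        ev = ev_frame("abx", times, np.ones(50), vclass="medication")
        stays = pd.DataFrame([{"stay_id": "s0", "patient_id": "p0",
                               "admit_ts": T0 - D, "discharge_ts": T0 + D}])
        fm = build_matrix(stays, ev, [VariableSpec("abx", "medication")], include_manual=False)
        assert {d.window for d in fm.descriptors} == {"1d", "3d", "7d"}


class TestTimeseries:
    def test_constant_series(self):
        discharge = T0 + 5 * D
        times = pd.date_range(T0, discharge, freq="2h")
        ev = ev_frame("x", times, np.full(len(times), 3.5))
        out = timeseries_features(ev, discharge, "high")
        for d, v in out.items():
            if d.statistic in ("median", "min", "max"):
                assert v == 3.5
            else:
                assert v == 0.0

    def test_exactly_15_columns(self):
        for horizon in ("high", "medium", "low"):
            ds = descriptors_for(VariableSpec("x", "timeseries", horizon=horizon))
            assert len(ds) == 15

    def test_empty_window_all_missing_single_point_trend_missing(self):
        discharge = T0 + 10 * D
        ev = ev_frame("x", [discharge - pd.Timedelta(hours=2)], [7.0])
        out = timeseries_features(ev, discharge, "high")
        by = {(d.statistic, d.window): v for d, v in out.items()}
        assert np.isnan(by[("trend_per_day", "4h")])
        assert by[("median", "4h")] == 7.0
        # nothing falls in no window?  the single point is within all three
        ev2 = ev_frame("x", [discharge - 30 * D], [7.0])
        out2 = timeseries_features(ev2, discharge, "high")
        assert all(np.isnan(v) for v in out2.values())

    def test_non_numeric_value_is_data_error(self):
        ev = ev_frame("x", [T0], ["abc"])
        with pytest.raises(FeaturizeError, match="x"):
            timeseries_features(ev, T0 + D, "low")

    def test_random_series_match_oracle(self, rng):
        for trial in range(200):
            discharge = T0 + pd.Timedelta(days=float(rng.uniform(1, 12)))
            n = int(rng.integers(1, 40))
            times = [discharge - pd.Timedelta(hours=float(h))
                     for h in rng.uniform(-24, 200, size=n)]  # some after discharge
            vals = rng.normal(50, 10, size=n)
            horizon = ("high", "medium", "low")[trial % 3]
            ev = ev_frame("x", times, vals)
            out = timeseries_features(
                ev.loc[ev["timestamp"] <= discharge], discharge, horizon
            )
            rows = [(t, v) for t, v in zip(times, vals) if t <= discharge]
            expected = oracles.naive_timeseries(rows, discharge, horizon)
            for d, got in out.items():
                want = expected[(d.statistic, d.window)]
                if np.isnan(want):
                    assert np.isnan(got), d
                else:
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-9), d


class TestFlow:
    def test_unit_window(self):
        discharge = T0 + 3 * D
        ev = ev_frame("urine", [discharge - 2 * H], [500.0], vclass="flow")
        out = flow_features(ev, discharge)
        by = {d.window: v for d, v in out.items()}
        assert by["1d"] == 500.0

    def test_three_day_scaling(self):
        discharge = T0 + 10 * D
        times = [discharge - pd.Timedelta(hours=h) for h in (30, 50, 70)]
        ev = ev_frame("urine", times, [200.0, 200.0, 200.0], vclass="flow")
        out = flow_features(ev, discharge)
        by = {d.window: v for d, v in out.items()}
        assert by["3d"] == pytest.approx(600.0 * 24 / 72)  # = 200/day

    def test_negative_volume_rejected(self):
        ev = ev_frame("urine", [T0], [-5.0], vclass="flow")
        with pytest.raises(FeaturizeError):
            flow_features(ev, T0 + D)

    def test_random_match_oracle(self, rng):
        for _ in range(100):
            discharge = T0 + 8 * D
            n = int(rng.integers(0, 25))
            times = [discharge - pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 250, n)]
            vals = rng.uniform(0, 800, size=n)
            ev = ev_frame("urine", times, vals, vclass="flow")
            out = {d.window: v for d, v in flow_features(ev, discharge).items()}
            want = oracles.naive_flow(list(zip(times, vals)), discharge)
            for w in ("1d", "3d", "7d"):
                assert out[w] == pytest.approx(want[w])


class TestMedication:
    def test_no_administrations(self):
        ev = ev_frame("abx", [], [], vclass="medication")
        out = medication_features(ev, T0)
        assert all(v == 0.0 for v in out.values())

    def test_three_distinct_drugs(self):
        discharge = T0 + D
        times = [discharge - i * H for i in (1, 2, 3, 4)]
        ev = ev_frame("abx", times, [1.0, 2.0, 3.0, 2.0], vclass="medication")
        out = {(d.statistic, d.window): v for d, v in medication_features(ev, discharge).items()}
        assert out[("unique_count", "1d")] == 3.0
        assert out[("indicator", "1d")] == 1.0

    def test_random_match_oracle(self, rng):
        for _ in range(100):
            discharge = T0 + 9 * D
            n = int(rng.integers(0, 30))
            times = [discharge - pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 250, n)]
            vals = rng.integers(1, 6, size=n).astype(float)
            ev = ev_frame("abx", times, vals, vclass="medication")
            out = {(d.statistic, d.window): v for d, v in medication_features(ev, discharge).items()}
            want = oracles.naive_medication(list(zip(times, vals)), discharge)
            for k, v in want.items():
                assert out[k] == v


class TestIntervention:
    def test_tube_at_discharge_days_since_zero(self):
        discharge = T0 + 4 * D
        times = pd.date_range(T0, discharge, freq="24h")
        ev = ev_frame("tube", times, np.ones(len(times)), vclass="intervention")
        out = {(d.statistic, d.window): v for d, v in intervention_features(ev, discharge).items()}
        assert out[("days_since_last", "history")] == 0.0
        assert out[("indicator", "3d")] == 1.0

    def test_never_performed_missing(self):
        ev = ev_frame("tube", [], [], vclass="intervention")
        out = {(d.statistic, d.window): v for d, v in intervention_features(ev, T0).items()}
        assert np.isnan(out[("days_since_last", "history")])
        assert out[("indicator", "7d")] == 0.0

    def test_random_match_oracle(self, rng):
        for _ in range(100):
            discharge = T0 + 12 * D
            n = int(rng.integers(0, 12))
            times = [discharge - pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 400, n)]
            vals = rng.uniform(0, 2, size=n)
            ev = ev_frame("tube", times, vals, vclass="intervention")
            out = {(d.statistic, d.window): v for d, v in intervention_features(ev, discharge).items()}
            want = oracles.naive_intervention(list(zip(times, vals)), discharge)
            for k, v in want.items():
                if isinstance(v, float) and np.isnan(v):
                    assert np.isnan(out[k]), k
                else:
                    assert out[k] == pytest.approx(v), k


class TestStatic:
    def test_single_record(self):
        ev = ev_frame("age", [T0], [63.0], vclass="static")
        out = static_features(ev, T0 + 5 * D, "patient")
        assert list(out.values())[0] == 63.0

    def test_last_value_wins(self):
        ev = ev_frame("weight", [T0, T0 + 2 * D], [80.0, 78.0], vclass="static")
        out = static_features(ev, T0 + 5 * D, "icu_stay", interval_start=T0)
        assert list(out.values())[0] == 78.0

    def test_random_match_oracle(self, rng):
        for _ in range(50):
            discharge = T0 + 6 * D
            n = int(rng.integers(0, 8))
            times = [T0 + pd.Timedelta(hours=float(h)) for h in rng.uniform(-100, 200, n)]
            vals = rng.normal(60, 10, size=n)
            ev = ev_frame("age", times, vals, vclass="static")
            got = list(static_features(ev, discharge, "patient").values())[0]
            want = oracles.naive_static(list(zip(times, vals)), discharge)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == want


class TestBuildMatrix:
    def _stays(self):
        return pd.DataFrame([{"stay_id": "s0", "patient_id": "p0",
                              "admit_ts": T0, "discharge_ts": T0 + 3 * D}])

    def test_column_counts_per_class(self):
        assert len(descriptors_for(VariableSpec("a", "timeseries", horizon="low"))) == 15
        assert len(descriptors_for(VariableSpec("b", "flow"))) == 3
        assert len(descriptors_for(VariableSpec("c", "medication"))) == 6
        assert len(descriptors_for(VariableSpec("d", "intervention"))) == 4
        assert len(descriptors_for(VariableSpec("e", "static"))) == 1

    def test_one_timeseries_plus_one_static_is_16_columns(self):
        ev = pd.concat([
            ev_frame("hr", pd.date_range(T0, periods=10, freq="1h"), np.arange(10.0)),
            ev_frame("age", [T0], [60.0], vclass="static"),
        ], ignore_index=True)
        fm = build_matrix(self._stays(), ev,
                          [VariableSpec("hr", "timeseries"), VariableSpec("age", "static")],
                          include_manual=False)
        assert fm.df.shape == (1, 16)

    def test_empty_event_log_gives_missing_timeseries_row(self):
        ev = ev_frame("hr", [], [])
        fm = build_matrix(self._stays(), ev, [VariableSpec("hr", "timeseries", horizon="high")],
                          include_manual=False)
        assert fm.df.shape == (1, 15)
        assert fm.df.isna().all().all()

    def test_unknown_variable_class_fails(self):
        with pytest.raises(FeaturizeError):
            VariableSpec("x", "notaclass")

    def test_unspecced_variable_fails(self):
        ev = ev_frame("mystery", [T0 + D], [1.0])
        with pytest.raises(FeaturizeError, match="mystery"):
            build_matrix(self._stays(), ev, [VariableSpec("hr", "timeseries")],
                         include_manual=False)

    def test_manual_los_feature(self):
        ev = ev_frame("age", [T0], [60.0], vclass="static")
        transfers = pd.DataFrame([{
            "patient_id": "p0", "hospital_stay_id": "h0", "unit_id": "W", "unit_type": "WARD",
            "admit_ts": T0 - 4 * D, "discharge_ts": T0, "disposition": "standard_care"}])
        fm = build_matrix(self._stays(), ev, [VariableSpec("age", "static")],
                          transfers=transfers, include_manual=True)
        col = f"{MANUAL_LOS_FEATURE}|manual|hospital_stay"
        assert fm.df[col].iloc[0] == pytest.approx(4.0)

    def test_truth_features_present_for_simulator_output(self, small_cohort):
        cfg, transfers, events, truth = small_cohort
        from icurisk.simulate import variable_specs_for
        elig = truth.stays
        fm = build_matrix(elig[["stay_id", "patient_id", "admit_ts", "discharge_ts"]],
                          events.loc[events["stay_id"].isin(set(elig["stay_id"]))],
                          variable_specs_for(cfg), include_manual=False)
        for t in cfg.truth_terms:
            assert t.feature.name in fm.df.columns


class TestInvariants:
    def test_causality_post_discharge_events_ignored(self, rng):
        stays = pd.DataFrame([{"stay_id": "s0", "patient_id": "p0",
                               "admit_ts": T0, "discharge_ts": T0 + 3 * D}])
        times = [T0 + pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 70, 30)]
        vals = rng.normal(size=30)
        ev = ev_frame("hr", times, vals)
        specs = [VariableSpec("hr", "timeseries", horizon="medium")]
        base = build_matrix(stays, ev, specs, include_manual=False)
        extra = ev_frame("hr", [T0 + 3 * D + pd.Timedelta(seconds=5)], [999.0])
        perturbed = build_matrix(stays, pd.concat([ev, extra], ignore_index=True),
                                 specs, include_manual=False)
        pd.testing.assert_frame_equal(base.df, perturbed.df)

    def test_window_nesting(self, rng):
        discharge = T0 + 5 * D
        for _ in range(30):
            n = int(rng.integers(2, 40))
            times = [discharge - pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 30, n)]
            ev = ev_frame("x", times, rng.normal(size=n))
            out = {(d.statistic, d.window): v
                   for d, v in timeseries_features(ev, discharge, "high").items()}
            if not np.isnan(out[("min", "4h")]):
                assert out[("min", "4h")] >= out[("min", "24h")]
                assert out[("max", "4h")] <= out[("max", "24h")]

    def test_full_matrix_equals_naive_featurizer(self, rng):
        """End-to-end equality with the brute-force oracle on a random log."""
        n_stays = 6
        stays = pd.DataFrame({
            "stay_id": [f"s{i}" for i in range(n_stays)],
            "patient_id": [f"p{i}" for i in range(n_stays)],
            "admit_ts": [T0 + i * 20 * D for i in range(n_stays)],
            "discharge_ts": [T0 + (i * 20 + 4) * D for i in range(n_stays)],
        })
        specs = [
            VariableSpec("hr", "timeseries", horizon="high"),
            VariableSpec("cr", "timeseries", horizon="low"),
            VariableSpec("urine", "flow"),
            VariableSpec("abx", "medication"),
            VariableSpec("tube", "intervention"),
            VariableSpec("age", "static", static_interval="patient"),
        ]
        frames = []
        raw = {}
        for i in range(n_stays):
            discharge = stays["discharge_ts"].iloc[i]
            for var, vclass in [("hr", "timeseries"), ("cr", "timeseries"),
                                ("urine", "flow"), ("abx", "medication"),
                                ("tube", "intervention"), ("age", "static")]:
                n = int(rng.integers(0, 25))
                times = [discharge - pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 300, n)]
                vals = (rng.integers(1, 5, n).astype(float) if vclass == "medication"
                        else rng.uniform(0, 100, n))
                frames.append(ev_frame(var, times, vals, stay=f"s{i}", pid=f"p{i}", vclass=vclass))
                raw[(f"s{i}", var)] = list(zip(times, vals))
        events = pd.concat([f for f in frames if len(f)], ignore_index=True)
        fm = build_matrix(stays, events, specs, include_manual=False)
        for i in range(n_stays):
            discharge = stays["discharge_ts"].iloc[i]
            sid = f"s{i}"
            row = fm.df.loc[sid]
            for var, horizon in [("hr", "high"), ("cr", "low")]:
                want = oracles.naive_timeseries(raw[(sid, var)], discharge, horizon)
                for (stat, w), v in want.items():
                    got = row[f"{var}|{stat}|{w}"]
                    assert (np.isnan(got) and np.isnan(v)) or got == pytest.approx(v), (var, stat, w)
            want = oracles.naive_flow(raw[(sid, "urine")], discharge)
            for w, v in want.items():
                assert row[f"urine|extrapolated_flow|{w}"] == pytest.approx(v)
            want = oracles.naive_medication(raw[(sid, "abx")], discharge)
            for (stat, w), v in want.items():
                assert row[f"abx|{stat}|{w}"] == v
            want = oracles.naive_intervention(raw[(sid, "tube")], discharge)
            for (stat, w), v in want.items():
                got = row[f"tube|{stat}|{w}"]
                assert (isinstance(v, float) and np.isnan(v) and np.isnan(got)) or got == pytest.approx(v)
            want = oracles.naive_static(raw[(sid, "age")], discharge)
            got = row["age|last_value|patient"]
            assert (np.isnan(want) and np.isnan(got)) or got == want
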