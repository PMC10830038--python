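"""Filtering ladder: rule examples, brute-force oracles, and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from telemax import telemetry as tm


def _track(xy, start="2019-01-01T00:00:00Z", step_min=60, dep="d1"):
    n = len(xy)
    ts = pd.date_range(start, periods=n, freq=f"{step_min}min", tz="UTC")
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "deployment_id": dep,
            "timestamp": ts,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lon": -107.5 + xy[:, 0] / 80_000.0,
            "lat": 43.0 + xy[:, 1] / 111_000.0,
            "fix_type": "GPS",
            "argos_class": "",
        }
    )


class TestArgosClassFilter:
    def test_low_classes_removed(self):
        df = _track(np.zeros((8, 2)))
        df["fix_type"] = ["GPS"] * 5 + ["Argos"] * 3
        df["argos_class"] = ["", "", "", "", "", "0", "0", "0"]
        kept, removed = tm.argos_class_filter(df)
        assert len(kept) == 5 and len(removed) == 3
        assert set(removed["removal_reason"]) == {"argos_class"}

    def test_one_of_each_class(self):
        df = _track(np.zeros((6, 2)))
        df["fix_type"] = "Argos"
        df["argos_class"] = ["3", "2", "1", "0", "A", "B"]
        kept, _ = tm.argos_class_filter(df)
        assert kept["argos_class"].tolist() == ["3", "2", "1"]

    def test_empty_input(self):
        df = _track(np.zeros((0, 2)))
        kept, removed = tm.argos_class_filter(df)
        assert len(kept) == 0 and len(removed) == 0

    def test_unknown_source_raises(self):
        df = _track(np.zeros((3, 2)))
        df.loc[1, "fix_type"] = "doppler?"
        with pytest.raises(ValueError, match="doppler"):
            tm.argos_class_filter(df)


def _spike_geometry(leg_m, angle_deg):
    """Out-and-back: A -> B -> C with interior angle at B and equal legs."""
    a = (0.0, 0.0)
    b = (leg_m, 0.0)
    th = math.radians(180.0 - angle_deg)
    c = (b[0] + leg_m * math.cos(th), b[1] + leg_m * math.sin(th))
    return _track([a, b, c, (200.0, 300.0), (400.0, 500.0)])


class TestSpikeFilter:
    def test_collinear_track_unchanged(self):
        df = _track([(i * 1000.0, 0.0) for i in range(6)])
        kept, removed = tm.spike_filter(df)
        assert len(removed) == 0 and len(kept) == 6

    def test_three_km_out_and_back_removed(self):
        df = _spike_geometry(3000.0, 10.0)
        kept, removed = tm.spike_filter(df)
        assert len(removed) == 1
        assert removed.index[0] == 1  # the turn point

    def test_two_km_legs_retained(self):
        df = _spike_geometry(2000.0, 10.0)
        _, removed = tm.spike_filter(df)
        assert len(removed) == 0

    def test_wide_angle_retained(self):
        df = _spike_geometry(6000.0, 40.0)
        _, removed = tm.spike_filter(df)
        assert len(removed) == 0

    def test_second_rule_fires_at_long_legs(self):
        # 20 deg: passes the 15-deg rule but fails the 25-deg/5-km rule
        df = _spike_geometry(6000.0, 20.0)
        _, removed = tm.spike_filter(df)
        assert len(removed) == 1

    def test_short_track_warns_unchanged(self):
        df = _track([(0.0, 0.0), (10.0, 0.0)])
        with pytest.warns(UserWarning, match="<3 fixes"):
            kept, removed = tm.spike_filter(df)
        assert len(kept) == 2 and len(removed) == 0

    def test_idempotent(self, rng):
        xy = np.cumsum(rng.normal(0, 800, size=(60, 2)), axis=0)
        xy[10] += 8000  # inject one spike
        df = _track(xy)
        once, _ = tm.spike_filter(df)
        twice, removed2 = tm.spike_filter(once)
        assert len(removed2) == 0
        pd.testing.assert_frame_equal(once, twice)


def _velocity_oracle(df, vmax):
    """Independent greedy pass, recursive formulation."""
    rows = df.sort_values("timestamp").to_dict("records")
    kept = [rows[0]]
    for r in rows[1:]:
        last = kept[-1]
        dt = (r["timestamp"] - last["timestamp"]).total_seconds()
        if dt <= 0:
            continue
        v = math.hypot(r["x"] - last["x"], r["y"] - last["y"]) / dt
        if v <= vmax:
            kept.append(r)
    return [r["timestamp"] for r in kept]


class TestVelocityFilter:
    def test_below_threshold_retained(self):
        df = _track([(0, 0), (1000, 0)], step_min=1)  # 16.7 m/s
        kept, _ = tm.velocity_filter(df, vmax=20.0)
        assert len(kept) == 2

    def test_above_threshold_removed(self):
        df = _track([(0, 0), (3000, 0)], step_min=1)  # 50 m/s
        kept, removed = tm.velocity_filter(df, vmax=40.0)
        assert len(kept) == 1 and removed["removal_reason"].tolist() == ["velocity"]

    @pytest.mark.parametrize("case", range(25))
    def test_matches_brute_force_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(5, 40))
        xy = np.cumsum(rng.normal(0, 1500, size=(n, 2)), axis=0)
        df = _track(xy, step_min=int(rng.integers(1, 30)))
        kept, _ = tm.velocity_filter(df, vmax=27.8)
        assert kept["timestamp"].tolist() == _velocity_oracle(df, 27.8)

    def test_idempotent_many_random_tracks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 2000, size=(30, 2)), axis=0)
            df = _track(xy, step_min=2)
            once, _ = tm.velocity_filter(df)
            twice, removed = tm.velocity_filter(once)
            assert len(removed) == 0


class TestHourlySubsample:
    def test_four_in_one_hour(self):
        df = _track(np.zeros((4, 2)), step_min=15)
        kept, _ = tm.hourly_subsample(df)
        assert len(kept) == 1

    def test_adjacent_hours_kept(self):
        df = _track(np.zeros((2, 2)), start="2019-01-01T09:59:00Z", step_min=2)
        kept, _ = tm.hourly_subsample(df)
        assert len(kept) == 2

    @pytest.mark.parametrize("case", range(10))
    def test_matches_per_hour_grouping_oracle(self, case):
        rng = np.random.default_rng(2000 + case)
        n = 60
        ts = pd.Timestamp("2019-01-01", tz="UTC") + pd.to_timedelta(
            np.sort(rng.integers(0, 72 * 3600, n)), unit="s"
        )
        df = _track(np.zeros((n, 2)))
        df["timestamp"] = ts
        kept, _ = tm.hourly_subsample(df)
        oracle = df.groupby(df["timestamp"].dt.floor("h"), group_keys=False).apply(
            lambda g: g.nsmallest(1, "timestamp")
        )
        assert sorted(kept["timestamp"]) == sorted(oracle["timestamp"])


class TestSeasonDaytime:
    def test_rules(self):
        # winter noon kept; near-sunrise removed; March dropped from both sets
        df = _track(np.zeros((3, 2)))
        df["timestamp"] = pd.to_datetime(
            ["2019-01-15T19:30:00Z", "2019-01-15T14:40:00Z", "2019-03-10T19:30:00Z"]
        ).tz_convert("UTC")
        winter, summer, removed = tm.season_daytime_filter(df)
        assert len(winter) == 1
        assert winter["timestamp"].dt.hour.iloc[0] == 19
        assert len(summer) == 0
        reasons = set(removed["removal_reason"])
        assert reasons == {"night_or_twilight", "off_season"}

    def test_summer_kept_separately_all_hours(self):
        df = _track(np.zeros((2, 2)))
        df["timestamp"] = pd.to_datetime(
            ["2018-07-01T03:00:00Z", "2018-07-01T19:00:00Z"]
        ).tz_convert("UTC")
        winter, summer, removed = tm.season_daytime_filter(df)
        assert len(summer) == 2 and len(winter) == 0 and len(removed) == 0


class TestBouts:
    def test_gap_free_track_single_bout(self):
        df = _track(np.zeros((60 * 24, 2)), step_min=60)
        assert len(tm.segment_bouts(df)) == 1

    def test_short_track_no_bout(self):
        df = _track(np.zeros((20 * 24, 2)), step_min=60)
        assert tm.segment_bouts(df) == []

    def test_gap_splits_into_two(self):
        a = _track(np.zeros((30 * 24, 2)), step_min=60)
        b = _track(np.zeros((30 * 24, 2)), start="2019-03-05T00:00:00Z", step_min=60)
        bouts = tm.segment_bouts(pd.concat([a, b], ignore_index=True))
        assert len(bouts) == 2


class TestRST:
    def test_stationary_cluster_all_sedentary(self, rng):
        xy = rng.normal(0, 300, size=(10 * 24, 2))  # 10 days within ~1 km
        bout = tm.segment_bouts(_track(xy), min_days=5)[0]
        out = tm.rst_classify(bout)
        assert (out["behavior"] == "sedentary").all()

    def test_straight_transit_flagged(self, rng):
        """Clusters joined by a 300-km constant-velocity leg at 15 m/s."""
        pre = rng.normal(0, 400, size=(15 * 24, 2))
        speed = 15.0 * 3600  # m per hourly fix
        n_leg = int(300_000 / speed)
        leg = np.column_stack(
            [np.linspace(speed, 300_000, n_leg), np.zeros(n_leg)]
        )
        post = np.array([300_000.0, 0.0]) + rng.normal(0, 400, size=(15 * 24, 2))
        xy = np.vstack([pre, leg, post])
        bout = tm.segment_bouts(_track(xy), min_days=5)[0]
        out = tm.rst_classify(bout).reset_index(drop=True)
        leg_states = out.loc[len(pre) : len(pre) + n_leg - 1, "behavior"]
        assert (leg_states == "transit").mean() > 0.7
        cluster_states = out.loc[: len(pre) - 5, "behavior"]
        assert (cluster_states == "sedentary").mean() > 0.9

    def test_accuracy_against_truth_labels(self, classified_sim):
        retained = classified_sim["retained"]
        bouts = tm.segment_bouts(retained)
        out = pd.concat([tm.rst_classify(b) for b in bouts])
        acc = (out["behavior"] == out["true_state"]).mean()
        assert acc > 0.8

    def test_invalid_radius(self, rng):
        bout = tm.segment_bouts(_track(rng.normal(0, 10, (24 * 30, 2))))[0]
        with pytest.raises(ValueError):
            tm.rst_classify(bout, radius_m=-1.0)


class TestThinning:
    def _day(self, rng):
        # 10 morning + 10 afternoon fixes on one winter day (UTC hours 15-23)
        ts = ["2019-01-10T%02d:%02d:00Z" % (h, m) for h, m in
              [(15, 5 * i) for i in range(10)] + [(20, 5 * i) for i in range(10)]]
        df = _track(np.zeros((20, 2)))
        df["timestamp"] = pd.to_datetime(ts).tz_convert("UTC")
        return df

    def test_two_retained_one_each_half(self, rng):
        df = tm.attribute_solar(self._day(rng))
        kept, _ = tm.thin_two_per_day(df, rng)
        assert len(kept) == 2
        noon = kept["solar_noon_min"].iloc[0]
        halves = sorted(kept["minute_of_day"] < noon)
        assert halves == [False, True]
        sep = kept["timestamp"].max() - kept["timestamp"].min()
        assert sep >= pd.Timedelta(hours=1)

    def test_single_half_day(self, rng):
        df = self._day(rng).iloc[10:]  # afternoon only
        kept, _ = tm.thin_two_per_day(df, rng)
        assert len(kept) == 1

    def test_deterministic_given_seed(self):
        df = self._day(np.random.default_rng(0))
        k1, _ = tm.thin_two_per_day(df, np.random.default_rng(55))
        k2, _ = tm.thin_two_per_day(df, np.random.default_rng(55))
        pd.testing.assert_frame_equal(k1, k2)


class TestSplit:
    def test_proportions_and_partition(self, rng):
        df = _track(np.zeros((100, 2)))
        train, test = tm.train_test_split(df, 0.75, rng)
        assert len(train) == 75 and len(test) == 25
        union = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(union, df)
        assert len(train.index.intersection(test.index)) == 0

    def test_same_seed_same_partition(self):
        df = _track(np.zeros((40, 2)))
        t1, _ = tm.train_test_split(df, 0.75, np.random.default_rng(9))
        t2, _ = tm.train_test_split(df, 0.75, np.random.default_rng(9))
        pd.testing.assert_frame_equal(t1, t2)


class TestAccounting:
    def test_removals_balance(self, small_sim):
        fixes = small_sim["fixes"]
        f1, r1 = tm.argos_class_filter(fixes)
        f2, r2 = tm.spike_filter(f1)
        f3, r3 = tm.velocity_filter(f2)
        f4, r4 = tm.hourly_subsample(f3)
        assert len(fixes) == len(f4) + len(r1) + len(r2) + len(r3) + len(r4)
        for r in (r1, r2, r3, r4):
            if len(r):
                assert r["removal_reason"].notna().all()

    def test_filters_never_alter_rows(self, small_sim):
        fixes = small_sim["fixes"]
        kept, _ = tm.argos_class_filter(fixes)
        cols = ["timestamp", "x", "y"]
        pd.testing.assert_frame_equal(kept[cols], fixes.loc[kept.index, cols])
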