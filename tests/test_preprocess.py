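"""Tests of the filtering and regularization chain on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from nestmove.model import ArgosErrorTable
from nestmove.preprocess import (clean_fixes, exclude_flagged, filter_dives,
                                 preprocess, project_to_plane, regularize,
                                 segment_tracks, speed_filter)
from nestmove.simulate import SimulationConfig, simulate_dataset


def fix_frame(times_h, x, y, animal="w1", cls="3", t0="2016-03-01T00:00:00"):
    base = np.datetime64(t0, "s")
    ts = base + (np.asarray(times_h, dtype=float) * 3600).astype("timedelta64[s]")
    return pd.DataFrame({"animal": animal, "timestamp": ts,
                         "x_km": np.asarray(x, float),
                         "y_km": np.asarray(y, float), "argos_class": cls})


class TestCleanFixes:
    def test_duplicate_timestamps_keep_first(self):
        df = fix_frame([0, 1, 1, 2], [0, 1, 99, 2], [0, 0, 0, 0])
        out, report = clean_fixes(df)
        assert len(out) == 3
        assert report["duplicate_timestamp"] == 1
        assert out["x_km"].tolist() == [0, 1, 2]  # first of the pair kept

    def test_empty_input(self):
        out, report = clean_fixes(fix_frame([], [], []))
        assert out.empty
        assert sum(report.values()) == 0

    def test_constructed_fixture_counts(self):
        # 100 fixes: 7 injected duplicates, 3 missing-coordinate rows
        rng = np.random.default_rng(0)
        df = fix_frame(np.arange(90), rng.normal(size=90), rng.normal(size=90))
        dups = df.iloc[rng.choice(90, 7, replace=False)]
        missing = fix_frame([200, 201, 202], [np.nan] * 3, [0.0] * 3)
        full = pd.concat([df, dups, missing], ignore_index=True)
        assert len(full) == 100
        out, report = clean_fixes(full)
        assert len(out) == 90
        assert report["duplicate_timestamp"] == 7
        assert report["missing_coords"] == 3

    def test_unknown_class_rejected_not_fatal(self):
        df = fix_frame([0, 1], [0, 1], [0, 0])
        df.loc[1, "argos_class"] = "Z"
        out, report = clean_fixes(df)
        assert len(out) == 1
        assert report["unknown_class"] == 1

    def test_land_mask_applied(self):
        df = fix_frame([0, 1, 2], [0, 100, 0], [0, 100, 0])
        out, report = clean_fixes(df, land_mask=lambda x, y: x > 50)
        assert len(out) == 2
        assert report["on_land"] == 1

    def test_idempotent(self):
        df = fix_frame([0, 1, 1, 2], [0, 1, 2, 3], [0, 0, 0, 0])
        once, _ = clean_fixes(df)
        twice, rep = clean_fixes(once)
        pd.testing.assert_frame_equal(once, twice)
        assert sum(rep.values()) == 0


class TestSpeedFilter:
    def test_pair_beyond_threshold_drops_later(self):
        df = fix_frame([0, 2], [0, 50], [0, 0])  # 25 km/h
        out, report = speed_filter(df)
        assert len(out) == 1
        assert out["x_km"].iloc[0] == 0
        assert report["speed_violation"] == 1

    def test_stationary_track_unchanged(self):
        df = fix_frame(np.arange(10), np.zeros(10), np.zeros(10))
        out, _ = speed_filter(df)
        assert len(out) == 10

    def test_teleport_spikes_removed_and_postcondition_holds(self):
        rng = np.random.default_rng(1)
        n = 120
        t = np.arange(n, dtype=float)  # hourly fixes
        x = np.cumsum(rng.normal(0, 2, n))  # ~2 km/h random walk
        y = np.cumsum(rng.normal(0, 2, n))
        spike_idx = [15, 40, 41, 80, 110]
        x2, y2 = x.copy(), y.copy()
        x2[spike_idx] += 500.0  # teleports
        out, report = speed_filter(fix_frame(t, x2, y2))
        assert report["speed_violation"] == len(spike_idx)
        assert len(out) == n - len(spike_idx)
        # brute-force postcondition: all remaining consecutive speeds <= 20
        tt = out["timestamp"].to_numpy("datetime64[s]").astype(float) / 3600
        dist = np.hypot(np.diff(out["x_km"]), np.diff(out["y_km"]))
        assert np.all(dist / np.diff(tt) <= 20.0 + 1e-9)

    def test_idempotent(self):
        df = fix_frame([0, 2, 3], [0, 50, 51], [0, 0, 0])
        once, _ = speed_filter(df)
        twice, rep = speed_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep["speed_violation"] == 0


class TestSegmentTracks:
    def test_continuous_track_single_segment(self):
        df = fix_frame(np.arange(0, 49, 2), np.zeros(25), np.zeros(25))
        out, report = segment_tracks(df)
        assert report["n_tracks"] == 1
        assert (out["track"] == 1).all()

    def test_gap_splits_and_short_halves_dropped(self):
        # 30-h record with a 13-h gap: two pieces of ~8.5 h each, both < 24 h
        times = np.concatenate([np.arange(0, 9, 0.5), np.arange(22, 30.5, 0.5)])
        df = fix_frame(times, np.zeros(len(times)), np.zeros(len(times)))
        out, report = segment_tracks(df)
        assert report["n_tracks"] == 0
        assert out.empty

    def test_three_animal_fixture_matches_hand_count(self):
        frames = [
            # w1: 48 h continuous -> 1 track
            fix_frame(np.arange(0, 49, 3), np.zeros(17), np.zeros(17), "w1"),
            # w2: 30 h, 13-h gap at 9 h -> 9-h and 8-h pieces, both dropped
            fix_frame([0, 4, 9, 22, 26, 30], np.zeros(6), np.zeros(6), "w2"),
            # w3: 100 h with one 20-h gap at 50 h -> two 25+-h tracks
            fix_frame(np.concatenate([np.arange(0, 51, 5), np.arange(70, 101, 5)]),
                      np.zeros(18), np.zeros(18), "w3"),
        ]
        out, report = segment_tracks(pd.concat(frames, ignore_index=True))
        assert report["n_tracks"] == 3
        per_animal = out.groupby("animal")["track"].nunique().to_dict()
        assert per_animal == {"w1": 1, "w3": 2}


class TestFilterDives:
    def dive_frame(self, depth, duration):
        n = len(depth)
        ts = np.datetime64("2016-03-01", "s") + np.arange(n).astype("timedelta64[s]")
        return pd.DataFrame({"animal": "w1", "timestamp": ts,
                             "depth_m": depth, "duration_s": duration,
                             "shape": 0})

    def test_boundary_depth_removed_strictly(self):
        out, _ = filter_dives(self.dive_frame([10.0, 10.01], [60.0, 60.0]))
        assert out["depth_m"].tolist() == [10.01]

    def test_boundary_duration_removed_strictly(self):
        out, _ = filter_dives(self.dive_frame([50.0, 50.0], [20.0, 20.01]))
        assert out["duration_s"].tolist() == [20.01]

    def test_record_depth_dive_retained(self):
        # the deepest observed dive on record for this system is a valid record
        out, _ = filter_dives(self.dive_frame([543.5], [300.0]))
        assert len(out) == 1

    def test_fixture_with_six_violations(self):
        depth = [50.0] * 14 + [5.0, 9.9, 10.0] + [50.0] * 3
        dur = [60.0] * 14 + [60.0] * 3 + [10.0, 19.0, 20.0]
        out, report = filter_dives(self.dive_frame(depth, dur))
        assert len(out) == 14
        assert report["too_shallow"] == 3
        assert report["too_short"] == 3

    def test_negative_values_logged_as_invalid(self):
        out, report = filter_dives(self.dive_frame([-5.0, 50.0], [60.0, -1.0]))
        assert out.empty
        assert report["invalid_record"] == 2

    def test_idempotent(self):
        df = self.dive_frame([5.0, 50.0, 80.0], [60.0, 10.0, 90.0])
        once, _ = filter_dives(df)
        twice, rep = filter_dives(once)
        pd.testing.assert_frame_equal(once, twice)
        assert sum(rep.values()) == 0


class TestExcludeFlagged:
    def test_empty_window_list_is_identity(self):
        df = fix_frame(np.arange(5), np.zeros(5), np.zeros(5))
        out, report = exclude_flagged(df, {})
        pd.testing.assert_frame_equal(out, df)
        assert report["flag_excluded"] == 0

    def test_window_covering_everything_empties_track(self):
        df = fix_frame(np.arange(5), np.zeros(5), np.zeros(5))
        out, _ = exclude_flagged(df, {"w1": [("2016-02-01", "2016-04-01")]})
        assert out.empty

    def test_overlapping_windows_merged_and_tail_removed(self):
        df = fix_frame(np.arange(100), np.zeros(100), np.zeros(100))
        # two overlapping windows covering hours 80..99 (the final 20%)
        windows = {"w1": [("2016-03-04T08:00:00", "2016-03-04T20:00:00"),
                          ("2016-03-04T15:00:00", "2016-03-05T03:00:00")]}
        out, report = exclude_flagged(df, windows)
        assert report["flag_excluded"] == 20
        assert len(out) == 80

    def test_other_animals_untouched(self):
        df = pd.concat([fix_frame(np.arange(5), np.zeros(5), np.zeros(5), "w1"),
                        fix_frame(np.arange(5), np.zeros(5), np.zeros(5), "w2")],
                       ignore_index=True)
        out, _ = exclude_flagged(df, {"w1": [("2016-02-01", "2016-04-01")]})
        assert set(out["animal"]) == {"w2"}


class TestRegularize:
    def make_track(self, times_h, dive_times_h=()):
        df = fix_frame(times_h, np.arange(len(times_h), dtype=float),
                       np.zeros(len(times_h)))
        df["track"] = 1
        base = np.datetime64("2016-03-01T00:00:00", "s")
        dts = base + (np.asarray(dive_times_h, float) * 3600).astype("timedelta64[s]")
        dives = pd.DataFrame({"animal": "w1", "timestamp": dts,
                              "depth_m": 50.0, "duration_s": 120.0})
        return df, dives

    def test_fix_at_interval_start_has_j_zero(self):
        # half-open intervals: a fix on a boundary opens the next interval
        # (j = 0); only the final endpoint closes its interval with j = 1
        df, dives = self.make_track([0, 6, 12])
        reg = regularize(df, dives)
        assert reg.n_intervals == 2
        assert reg.fix_interval.tolist() == [1, 2, 2]
        assert reg.fix_j.tolist() == [0.0, 0.0, 1.0]

    def test_final_endpoint_closes_last_interval(self):
        df, dives = self.make_track([0, 12])
        reg = regularize(df, dives)
        assert reg.n_intervals == 2
        assert reg.fix_interval[-1] == 2
        assert reg.fix_j[-1] == 1.0

    def test_thirty_hour_track_and_dive_assignment(self):
        df, dives = self.make_track([0, 10, 20, 30], dive_times_h=[13.0])
        reg = regularize(df, dives)
        assert reg.n_intervals == 5
        assert reg.dive_interval.tolist() == [3]
        assert reg.dive_order.tolist() == [1]

    def test_dives_outside_span_dropped_and_counted(self):
        df, dives = self.make_track([0, 24], dive_times_h=[-1.0, 5.0, 30.0])
        reg = regularize(df, dives)
        assert reg.dive_interval.tolist() == [1]
        assert reg.n_dropped_dives == 2

    def test_within_interval_order_counts_up(self):
        df, dives = self.make_track([0, 12], dive_times_h=[1, 2, 3, 8])
        reg = regularize(df, dives)
        assert reg.dive_interval.tolist() == [1, 1, 1, 2]
        assert reg.dive_order.tolist() == [1, 2, 3, 1]


class TestProjection:
    def test_distances_match_haversine(self):
        lon = np.array([-64.0, -63.5, -63.0])
        lat = np.array([-64.8, -64.9, -65.2])
        df = pd.DataFrame({"lon": lon, "lat": lat})
        out = project_to_plane(df, center=(-63.5, -64.9))
        # independent haversine from the center
        R = 6371.0088
        lam, phi = np.radians(lon), np.radians(lat)
        lam0, phi0 = np.radians(-63.5), np.radians(-64.9)
        hav = 2 * R * np.arcsin(np.sqrt(
            np.sin((phi - phi0) / 2) ** 2
            + np.cos(phi0) * np.cos(phi) * np.sin((lam - lam0) / 2) ** 2))
        dist = np.hypot(out["x_km"], out["y_km"])
        assert np.allclose(dist, hav, rtol=1e-9)
        assert out["x_km"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_planar_input_passthrough(self):
        df = fix_frame([0], [1.0], [2.0])
        out = project_to_plane(df)
        pd.testing.assert_frame_equal(out, df)


class TestRoundTrip:
    def test_clean_synthetic_dataset_passes_unchanged(self):
        # low-noise fixes and a slow walk: nothing violates any filter
        table = ArgosErrorTable(sd_km={c: 1e-3 for c in ("3", "2", "1", "0",
                                                         "A", "B")})
        cfg = SimulationConfig(n_animals=2, steps_per_animal=30,
                               fixes_per_interval_rate=4.0,
                               dives_per_interval_rate=3.0,
                               missing_interval_prob=0.0,
                               error_table=table, seed=17)
        ds = simulate_dataset(cfg)
        tracks, report = preprocess(ds.fixes, ds.dives)
        assert report["clean"] == {"missing_coords": 0, "unknown_class": 0,
                                   "duplicate_timestamp": 0, "on_land": 0}
        assert report["speed"]["speed_violation"] == 0
        assert report["segments"]["n_tracks"] == 2
        assert sum(report["dives"].values()) == 0
        assert sum(t.fix_x.size for t in tracks) == len(ds.fixes)
        # dives survive the filters; only those outside a track's fix span
        # (before the first fix) can drop out at regularization
        expected_inside = 0
        for t in tracks:
            d = ds.dives[ds.dives["animal"] == t.animal]
            ts = d["timestamp"].to_numpy("datetime64[s]")
            hi = t.t0 + np.timedelta64(int(t.n_intervals * 6 * 3600), "s")
            expected_inside += int(((ts >= t.t0) & (ts <= hi)).sum())
        assert sum(t.dive_depth.size for t in tracks) == expected_inside
        assert sum(report["dives"].values()) == 0


class TestHypothesisProperties:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_speed_filter_postcondition_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        t = np.cumsum(rng.uniform(0.2, 3.0, n))
        x = np.cumsum(rng.normal(0, rng.uniform(1, 30), n))
        y = np.cumsum(rng.normal(0, rng.uniform(1, 30), n))
        out, _ = speed_filter(fix_frame(t, x, y))
        tt = out["timestamp"].to_numpy("datetime64[s]").astype(float) / 3600
        if len(out) > 1:
            dist = np.hypot(np.diff(out["x_km"]), np.diff(out["y_km"]))
            assert np.all(dist / np.diff(tt) <= 20.0 + 1e-9)
        again, rep = speed_filter(out)
        assert rep["speed_violation"] == 0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_regularize_assigns_every_instant_once(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(np.concatenate([[0.0],
                                          rng.uniform(0, 72, 20), [72.0]]))
        df = fix_frame(times, rng.normal(size=times.size),
                       rng.normal(size=times.size))
        df["track"] = 1
        dive_times = rng.uniform(0, 72, 30)
        base = np.datetime64("2016-03-01T00:00:00", "s")
        dives = pd.DataFrame({
            "animal": "w1",
            "timestamp": base + (dive_times * 3600).astype("timedelta64[s]"),
            "depth_m": 50.0, "duration_s": 60.0})
        reg = regularize(df, dives)
        assert np.all((reg.fix_j >= 0) & (reg.fix_j <= 1))
        assert np.all((reg.fix_interval >= 1)
                      & (reg.fix_interval <= reg.n_intervals))
        assert reg.dive_interval.size + reg.n_dropped_dives == len(dives)
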