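import numpy as np
import pytest

from adlsense.features import (
    AppEvent,
    MissingModalityError,
    ScreenEvent,
    appliance_elapsed_feature,
    assemble_features,
    elapsed_since_feature,
    light_mean_feature,
    phone_usage_feature,
    power_to_events,
    preset_feature_names,
    reconstruct_usage_intervals,
    room_light_binary,
    room_location_feature,
    step_feature,
)
from adlsense.io_streams import ROOMS
from conftest import series_from_array


class TestUsageIntervals:
    def test_no_app_events_no_intervals(self):
        assert reconstruct_usage_intervals([], [ScreenEvent(10, "off")]) == []

    def test_single_app_closed_by_screen_off(self):
        out = reconstruct_usage_intervals([AppEvent(0, "mail")], [ScreenEvent(60, "off")])
        assert [(i.app, i.start_t, i.end_t) for i in out] == [("mail", 0, 60)]

    def test_app_switch_then_lock(self):
        out = reconstruct_usage_intervals(
            [AppEvent(0, "A"), AppEvent(30, "B")], [ScreenEvent(50, "locked")]
        )
        assert [(i.app, i.start_t, i.end_t) for i in out] == [("A", 0, 30), ("B", 30, 50)]

    def test_system_utility_filtered(self):
        out = reconstruct_usage_intervals(
            [AppEvent(0, "A"), AppEvent(10, "keyboard")], [ScreenEvent(50, "locked")]
        )
        assert [(i.app, i.start_t, i.end_t) for i in out] == [("A", 0, 50)]

    def test_screen_on_unlock_do_not_close(self):
        out = reconstruct_usage_intervals(
            [AppEvent(0, "A")],
            [ScreenEvent(10, "on"), ScreenEvent(20, "unlocked"), ScreenEvent(40, "off")],
        )
        assert [(i.app, i.start_t, i.end_t) for i in out] == [("A", 0, 40)]

    def test_duplicate_foreground_events_merged(self):
        out = reconstruct_usage_intervals(
            [AppEvent(0, "A"), AppEvent(15, "A")], [ScreenEvent(30, "off")]
        )
        assert [(i.app, i.start_t, i.end_t) for i in out] == [("A", 0, 30)]

    def test_never_overlapping_and_starts_at_app_events(self, rng):
        """Sweep-line oracle over 1000 random event sequences."""
        for _ in range(1000):
            n_app = int(rng.integers(0, 6))
            n_scr = int(rng.integers(0, 6))
            apps = [AppEvent(float(t), str(rng.choice(["A", "B", "keyboard"])))
                    for t in np.sort(rng.uniform(0, 100, n_app))]
            screens = [ScreenEvent(float(t), str(rng.choice(["on", "off", "locked", "unlocked"])))
                       for t in rng.uniform(0, 100, n_scr)]
            out = reconstruct_usage_intervals(apps, screens, session_end=120.0)
            for a, b in zip(out, out[1:]):
                assert a.end_t <= b.start_t  # non-overlapping
            app_starts = {a.t for a in apps if a.app != "keyboard"}
            for iv in out:
                assert iv.start_t in app_starts
            # oracle: at the midpoint of each interval, the last event at or
            # before it must be a non-utility app event with no closing
            # screen event in between
            events = sorted(
                [(a.t, "app", a.app) for a in apps if a.app != "keyboard"]
                + [(s.t, "off", None) for s in screens if s.state in ("off", "locked")]
            )
            for iv in out:
                mid = (iv.start_t + iv.end_t) / 2
                last = [e for e in events if e[0] <= mid][-1]
                assert last[1] == "app" and last[2] == iv.app


class TestPointFeatures:
    def test_phone_usage_inside_interval(self):
        ivs = reconstruct_usage_intervals([AppEvent(0, "A")], [ScreenEvent(60, "off")])
        assert phone_usage_feature(ivs, 30) == 1
        assert phone_usage_feature(ivs, 60) == 0  # half-open end
        assert phone_usage_feature([], 30) == 0

    def test_step_count_half_open(self):
        s = series_from_array([0.5, 1.0, 2.0, 2.9, 3.0], np.ones(5), "step", duration=10)
        assert step_feature(s, 0.0) == 4
        assert step_feature(s, 3.0) == 1  # the t=3.0 event falls in the next bin

    def test_light_mean_and_carry_forward(self):
        s = series_from_array([0.0, 1.0, 2.0], [100, 200, 300], "light_phone", duration=60)
        assert light_mean_feature(s, 0.0) == pytest.approx(200.0)
        assert light_mean_feature(s, 30.0) == pytest.approx(300.0)  # carry last
        empty = series_from_array([], np.empty((0, 1)), "light_phone", duration=60)
        assert light_mean_feature(empty, 0.0) == 0.0

    def test_elapsed_since(self):
        events = np.array([1000.0])
        assert elapsed_since_feature(events, 1000.0 + 3600.0) == pytest.approx(3600 / 43200)
        assert elapsed_since_feature(events, 1000.0) == 0.0
        assert elapsed_since_feature(np.array([]), 500.0) == 1.0
        assert elapsed_since_feature(events, 1000.0 + 1e6) == 1.0  # capped

    def test_room_location_lookup(self):
        from adlsense.io_streams import SensorSample, SensorSeries

        s = SensorSeries("location", [SensorSample(0.0, ("kitchen",)),
                                      SensorSample(100.0, ("living_room",))], duration=200)
        assert room_location_feature(s, 50) == "kitchen"
        assert room_location_feature(s, 150) == "living_room"
        assert room_location_feature(s, -1) == "unknown"

    def test_room_light_state(self):
        s = series_from_array([10.0, 30.0], [1.0, 0.0], "light_bathroom", duration=60)
        assert room_light_binary(s, 20) == 1
        assert room_light_binary(s, 40) == 0
        assert room_light_binary(s, 5) == 0


class TestPowerEvents:
    def test_always_below_threshold(self):
        s = series_from_array([0, 10, 20], [1, 2, 1], "power_tv", duration=30)
        triggers, intervals = power_to_events(s)
        assert len(triggers) == 0 and intervals == []

    def test_single_pulse_one_trigger(self):
        s = series_from_array([0, 10, 20, 30], [1, 1500, 1500, 1], "power_tv", duration=40)
        triggers, intervals = power_to_events(s)
        assert list(triggers) == [10.0]
        assert intervals == [(10.0, 30.0)]

    def test_two_pulses_two_triggers(self):
        s = series_from_array([0, 10, 20, 30, 40], [1, 1500, 1, 1500, 1], "power_tv", duration=50)
        triggers, _ = power_to_events(s)
        assert list(triggers) == [10.0, 30.0]

    def test_elapsed_zero_during_use(self):
        s = series_from_array([0, 10, 20, 30], [1, 1500, 1500, 1], "power_tv", duration=4000)
        assert appliance_elapsed_feature(s, 15.0) == 0.0
        assert appliance_elapsed_feature(s, 30.0 + 432.0) == pytest.approx(432 / 43200)
        assert appliance_elapsed_feature(s, 5.0) == 1.0  # nothing prior


class TestAssemble:
    def test_probs_only_width(self, routine_session):
        fs = assemble_features(routine_session.bundle, routine_session.lowlevel_probs_3s,
                               "probs_only", 0.0)
        assert fs.matrix.shape == (200, len(routine_session.lowlevel_probs_3s.classes))

    def test_probs_location_width(self, routine_session):
        fs = assemble_features(routine_session.bundle, routine_session.lowlevel_probs_3s,
                               "probs_location", 0.0)
        n_probs = len(routine_session.lowlevel_probs_3s.classes)
        assert fs.matrix.shape == (200, n_probs + len(ROOMS) + 1)  # + unknown

    def test_ambient_only_excludes_phone_features(self):
        names = preset_feature_names("ambient_only", ())
        assert not any(n in names for n in ("phone_usage", "steps", "light_phone"))
        assert not any(n.startswith("p_") for n in names)

    def test_missing_modality_named(self, routine_session):
        bundle = routine_session.bundle
        stripped = type(bundle)(
            participant_id=bundle.participant_id,
            streams={k: v for k, v in bundle.streams.items() if k != "location"},
            adl_labels=bundle.adl_labels,
            duration=bundle.duration,
        )
        with pytest.raises(MissingModalityError, match="location"):
            assemble_features(stripped, routine_session.lowlevel_probs_3s,
                              "probs_location", 0.0)

    def test_feature_ranges(self, routine_session):
        fs = assemble_features(routine_session.bundle, routine_session.lowlevel_probs_3s,
                               "all", 0.0)
        m = dict(zip(fs.feature_names, fs.matrix.T))
        for name, col in m.items():
            if name.startswith(("room_", "light_bathroom", "light_toilet")) or name == "phone_usage":
                assert set(np.unique(col)) <= {0.0, 1.0}
            if name.endswith("_elapsed"):
                assert col.min() >= 0.0 and col.max() <= 1.0
        probs = np.column_stack([m[n] for n in fs.feature_names if n.startswith("p_")])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_preset_rejected(self, routine_session):
        with pytest.raises(ValueError, match="preset"):
            assemble_features(routine_session.bundle, routine_session.lowlevel_probs_3s,
                              "everything", 0.0)
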