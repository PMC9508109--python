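"""Event detection, stride segmentation, normalization and event windows."""

import numpy as np
import pytest

from quailkin.strides import (NormalizedStride,
                              StrideEvents, aggregate_mean_curves,
                              detect_events, extract_event_windows,
                              mirror_to_left, normalize_stride,
                              segment_strides)


class TestDetectEvents:
    def test_matches_generator_truth_within_one_frame(self, skeleton,
                                                      level_template):
        from quailkin.simulate import simulate_trial
        trial = simulate_trial(skeleton, level_template, fps=500.0,
                               n_strides=4, seed=0)
        T = level_template.stride_duration
        for leg in ("l", "r"):
            det = detect_events(trial.landmarks[f"mto_{leg}"], 500.0,
                                body_speed=level_template.speed)
            true_td = trial.events.touchdowns[leg] + [
                int(round(4 * T * 500.0))]
            true_to = trial.events.toeoffs[leg]
            for d in det["touchdowns"]:
                assert min(abs(d - t) for t in true_td) <= 1
            for d in det["toeoffs"]:
                assert min(abs(d - t) for t in true_to) <= 1
            # every interior true event is found
            n = trial.n_frames
            for t in true_td[1:-1]:
                assert min(abs(d - t) for d in det["touchdowns"]) <= 1
            for t in true_to[1:-1]:
                assert min(abs(d - t) for d in det["toeoffs"]) <= 1

    def test_airborne_trajectory_raises(self):
        toe = np.zeros((100, 3))
        toe[:, 2] = 0.05
        with pytest.raises(ValueError, match="no contacts"):
            detect_events(toe, 500.0, body_speed=0.65)

    def test_provided_events_bypass(self, level_trial):
        out = detect_events(level_trial.landmarks["mto_l"], 500.0,
                            body_speed=0.65, events=level_trial.events,
                            leg="l")
        assert out["touchdowns"] == list(level_trial.events.touchdowns["l"])


class TestStrideEvents:
    def test_non_alternating_rejected(self):
        with pytest.raises(ValueError, match="alternate"):
            StrideEvents(touchdowns={"l": [0, 50]}, toeoffs={"l": [60]})

    def test_roles_must_be_exclusive(self):
        with pytest.raises(ValueError, match="roles"):
            StrideEvents(touchdowns={"l": [0]}, toeoffs={"l": [10]},
                         roles={"l": "trailing", "r": "trailing"})


class TestSegmentStrides:
    def test_level_three_cycles_give_two_strides_per_leg(self):
        ev = StrideEvents(
            touchdowns={"l": [0, 100, 200], "r": [50, 150, 250]},
            toeoffs={"l": [60, 160, 260], "r": [10, 110, 210]})
        out = segment_strides(ev, "level")
        assert len(out) == 4
        assert (0, 100, "l") in out and (50, 150, "r") in out

    def test_step_trial_trailing_and_leading(self, skeleton):
        from quailkin.gait import make_gait_template
        from quailkin.simulate import simulate_trial
        trial = simulate_trial(skeleton, make_gait_template("up_5cm"),
                               fps=500.0, n_strides=4)
        trailing = segment_strides(trial.events, "trailing")
        leading = segment_strides(trial.events, "leading")
        assert len(trailing) == 1 and len(leading) == 1
        shift = trial.events.terrain_shift_frame
        a, b, leg = trailing[0]
        assert a <= shift <= b and leg == "l"
        a, b, leg = leading[0]
        assert a <= shift <= b and leg == "r"

    def test_role_requires_step_trial(self, level_trial):
        with pytest.raises(ValueError, match="terrain shift"):
            segment_strides(level_trial.events, "trailing")


class TestNormalizeStride:
    def test_exactly_100_samples_and_linear_ramp(self):
        st = normalize_stride(np.arange(100.0), "x")
        assert st.values.shape == (100,)
        np.testing.assert_allclose(st.values, np.arange(100.0), atol=1e-12)
        st2 = normalize_stride(np.arange(37.0), "x")
        assert len(st2.values) == 100
        np.testing.assert_allclose(st2.values, np.linspace(0, 36, 100),
                                   atol=1e-12)

    def test_endpoints_and_extrema_preserved(self):
        # 34 samples: the input knots k/33 all lie on the 100-point grid
        # j/99, so the piecewise-linear extrema are preserved exactly
        y = np.zeros(34)
        y[7], y[21], y[-1] = 5.0, 8.0, 1.0
        st = normalize_stride(y, "x")
        assert st.values[0] == 0.0 and st.values[-1] == 1.0
        assert st.values.max() == pytest.approx(8.0)
        assert st.values.min() == pytest.approx(0.0)

    def test_missing_spans_remain_missing(self):
        y = np.arange(50.0)
        y[20:25] = np.nan
        st = normalize_stride(y, "x")
        phase_lo, phase_hi = 19 / 49 * 100, 25 / 49 * 100
        gap = st.values[int(np.ceil(phase_lo)) + 1:int(phase_hi) - 1]
        assert np.isnan(gap).all()
        assert np.isfinite(st.values[:int(phase_lo)]).all()

    def test_event_phases_converted(self):
        st = normalize_stride(np.arange(38.0), "x",
                              events_in_window={"td": 0, "to": 23})
        assert st.event_phases["td"] == 0.0
        assert st.event_phases["to"] == pytest.approx(23 / 37 * 100)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            normalize_stride(np.full(10, np.nan), "x")


class TestMirrorToLeft:
    def _stride(self, variable, side):
        return NormalizedStride(variable=variable, side=side, role="level",
                                values=np.linspace(-1, 1, 100),
                                event_phases={})

    def test_left_input_is_identity(self):
        st = self._stride("hip_abduction", "l")
        assert mirror_to_left(st) is st

    def test_right_negates_x_and_z_rotations_only(self):
        for var, flips in [("hip_abduction", True), ("hip_mediolateral", True),
                           ("pelvis_roll", True), ("pelvis_yaw", True),
                           ("hip_flexion", False), ("knee", False),
                           ("eff_leg_angle", False)]:
            st = self._stride(var, "r")
            out = mirror_to_left(st)
            expected = -st.values if flips else st.values
            np.testing.assert_array_equal(out.values, expected)
            assert out.mirrored

    def test_double_mirror_is_identity(self):
        st = self._stride("pelvis_roll", "r")
        back = mirror_to_left(mirror_to_left(st))
        np.testing.assert_array_equal(back.values, st.values)
        assert not back.mirrored


class TestAggregateMeanCurves:
    def _stride(self, values):
        return NormalizedStride(variable="x", side="l", role="level",
                                values=values, event_phases={})

    def test_single_stride(self):
        v = np.linspace(0, 1, 100)
        out = aggregate_mean_curves([self._stride(v)])
        np.testing.assert_allclose(out["mean"], v)
        assert (out["sd"] == 0).all() and (out["n"] == 1).all()

    def test_opposite_curves_average_to_zero(self):
        v = np.sin(np.linspace(0, 6, 100))
        out = aggregate_mean_curves([self._stride(v), self._stride(-v)])
        np.testing.assert_allclose(out["mean"], 0.0, atol=1e-12)

    def test_missing_values_reduce_pointwise_n(self):
        v = np.ones(100)
        w = np.ones(100)
        w[:10] = np.nan
        out = aggregate_mean_curves([self._stride(v), self._stride(w)])
        assert list(out["n"][:10]) == [1] * 10
        assert list(out["n"][10:20]) == [2] * 10


class TestEventWindows:
    def _stride(self, role, to_phase=62.0):
        return NormalizedStride(variable="x", side="l", role=role,
                                values=np.arange(100.0),
                                event_phases={"td": 0.0, "to": to_phase})

    def test_leading_events_td_truncated_and_e85(self):
        wins = {w.event: w for w in extract_event_windows(self._stride("leading"))}
        assert set(wins) == {"td", "e85"}
        assert wins["td"].truncated and len(wins["td"].values) == 5
        np.testing.assert_array_equal(wins["e85"].values,
                                      np.arange(81.0, 90.0))

    def test_trailing_events_e15_and_to(self):
        wins = {w.event: w for w in extract_event_windows(self._stride("trailing"))}
        assert set(wins) == {"e15", "to"}
        np.testing.assert_array_equal(wins["e15"].values,
                                      np.arange(11.0, 20.0))
        assert not wins["e15"].truncated
        np.testing.assert_array_equal(wins["to"].values,
                                      np.arange(58.0, 67.0))

    def test_constant_curve_windows_constant(self):
        st = NormalizedStride(variable="x", side="l", role="trailing",
                              values=np.full(100, 7.0),
                              event_phases={"to": 62.0})
        for w in extract_event_windows(st):
            assert (w.values == 7.0).all()
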