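"""Behaviour of the synthetic pressure-sequence generator."""

import numpy as np
import pytest

from ipmap import (
    BodyModel,
    Landmark,
    NATIVE_PITCH_MM,
    SimulationScript,
    TRANSITION_LABEL,
    ValidationError,
    contact_area,
    cop,
    make_cohort,
    peak_pressure,
    render_static_frame,
    simulate_sequence,
)
from tests.conftest import SHORT_SCRIPT

TWO_POSTURE_SCRIPT = SimulationScript(
    segments=(("supine", 60.0), ("high_sitting", 60.0)), transition_duration=5.0
)


class TestRenderStaticFrame:
    def test_single_landmark_peak_equals_scaled_load(self, foam):
        # landmark placed exactly on a cell center: peak pressure = total_load * weight
        x_target = 59.5 * NATIVE_PITCH_MM  # center of row 59
        head_offset = (118 * NATIVE_PITCH_MM - 1720.0) / 2.0
        frac = (x_target - head_offset) / 1720.0
        body = BodyModel(
            landmarks=(Landmark("sacrum", frac, 7.95, 1.0, 30.0),),
            body_length=1720.0,
            total_load=100.0,
        )
        f = render_static_frame(body, "supine", foam)
        assert peak_pressure(f) == pytest.approx(100.0, abs=1e-6)

    def test_air_immerses_more_than_foam(self, body, foam, air):
        f_foam = render_static_frame(body, "supine", foam)
        f_air = render_static_frame(body, "supine", air)
        assert contact_area(f_air, 20.0) > contact_area(f_foam, 20.0)
        assert peak_pressure(f_air) < peak_pressure(f_foam)

    def test_lateral_sides_are_mirror_images(self, body, foam):
        left = render_static_frame(body, "lateral_left", foam)
        right = render_static_frame(body, "lateral_right", foam)
        np.testing.assert_allclose(left.values, right.values[:, ::-1], atol=1e-9)

    def test_postures_are_pairwise_separable(self, body, foam, air):
        """Each posture pair differs by > 2 pitches of longitudinal COP or
        > 10% of contact area - the classification task is well-posed."""
        for immersion in (foam, air):
            frames = {
                p: render_static_frame(body, p, immersion)
                for p in ("supine", "high_sitting", "lateral_right")
            }
            postures = list(frames)
            for i, a in enumerate(postures):
                for b in postures[i + 1 :]:
                    d_cop = abs(cop(frames[a])[0] - cop(frames[b])[0])
                    area_a = contact_area(frames[a], 5.0)
                    area_b = contact_area(frames[b], 5.0)
                    d_area = abs(area_a - area_b) / max(area_a, area_b)
                    assert d_cop > 2 * NATIVE_PITCH_MM or d_area > 0.10, (a, b)

    def test_off_mat_landmark_is_an_error(self, foam):
        body = BodyModel(
            landmarks=(Landmark("head", 0.0, 500.0, 1.0, 50.0),), body_length=1720.0
        )
        with pytest.raises(ValidationError, match="off the mat"):
            render_static_frame(body, "supine", foam)


class TestSimulateSequence:
    def test_frame_count_and_event_time(self, body, foam):
        seq = simulate_sequence(body, foam, TWO_POSTURE_SCRIPT, seed=0)
        assert len(seq) == 125  # 60 + 5 + 60 seconds at 1 Hz
        assert seq.event_times == (62.5,)

    def test_sensor_range_rule_on_every_frame(self, body, air):
        seq = simulate_sequence(body, air, SHORT_SCRIPT, noise_sd=2.0, seed=3)
        stacked = seq.pressures()
        assert not np.any((stacked > 0) & (stacked < 5.0))
        assert stacked.max() <= 200.0

    def test_noiseless_segments_are_static(self, body, foam):
        seq = simulate_sequence(body, foam, TWO_POSTURE_SCRIPT, noise_sd=0.0, seed=0)
        first_segment = [
            f.values for f, lab in zip(seq.frames, seq.posture_labels) if lab == "supine"
        ][:60]
        for v in first_segment[1:]:
            np.testing.assert_array_equal(v, first_segment[0])

    def test_seed_contract(self, body, foam):
        a = simulate_sequence(body, foam, SHORT_SCRIPT, seed=5)
        b = simulate_sequence(body, foam, SHORT_SCRIPT, seed=5)
        c = simulate_sequence(body, foam, SHORT_SCRIPT, seed=6)
        assert a == b
        assert any(
            not np.array_equal(x.values, y.values) for x, y in zip(a.frames, c.frames)
        )

    def test_events_sit_at_transition_label_midpoints(self, body, foam):
        seq = simulate_sequence(body, foam, SHORT_SCRIPT, seed=1)
        times = seq.times()
        labels = np.array(seq.posture_labels)
        # contiguous runs of 'transition' frames
        runs = []
        in_run = False
        for i, lab in enumerate(labels):
            if lab == TRANSITION_LABEL and not in_run:
                runs.append([i, i])
                in_run = True
            elif lab == TRANSITION_LABEL:
                runs[-1][1] = i
            else:
                in_run = False
        assert len(runs) == len(seq.event_times)
        for (start, end), event in zip(runs, seq.event_times):
            assert times[start] <= event <= times[end] + 1.0 / seq.frequency

    def test_transition_artifact_raises_midfade_peak(self, body, foam):
        quiet = simulate_sequence(
            body, foam, TWO_POSTURE_SCRIPT, noise_sd=0.0, seed=0, artifact_weight=0.0
        )
        vigorous = simulate_sequence(
            body, foam, TWO_POSTURE_SCRIPT, noise_sd=0.0, seed=0, artifact_weight=2.5
        )
        mid = 62  # frame nearest the fade midpoint at 62.5 s
        assert peak_pressure(vigorous.frames[mid]) > peak_pressure(quiet.frames[mid])
        # artifact vanishes outside the fade: static frames identical
        np.testing.assert_array_equal(quiet.frames[0].values, vigorous.frames[0].values)


class TestMakeCohort:
    def test_cohort_construction(self):
        cohort = make_cohort(5, regime="foam", seed=2, script=SHORT_SCRIPT)
        assert len(cohort) == 5
        assert len({seq.subject for seq in cohort}) == 5
        assert all(seq.posture_labels == cohort[0].posture_labels for seq in cohort)
        # bodies differ: static pressure fields differ across subjects
        assert not np.array_equal(cohort[0].frames[0].values, cohort[1].frames[0].values)

    def test_cohort_reproducible_from_seed(self):
        a = make_cohort(2, regime="air", seed=9, script=SHORT_SCRIPT)
        b = make_cohort(2, regime="air", seed=9, script=SHORT_SCRIPT)
        assert all(x == y for x, y in zip(a, b))

    def test_air_cohort_has_larger_contact_area(self):
        foam = make_cohort(3, regime="foam", seed=4, script=SHORT_SCRIPT)
        air = make_cohort(3, regime="air", seed=4, script=SHORT_SCRIPT)

        def mean_area(cohort):
            return np.mean(
                [contact_area(seq.frames[0], 20.0) for seq in cohort]
            )

        assert mean_area(air) > mean_area(foam)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValidationError):
            make_cohort(0)
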