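"""Tracking tests: detection, linking, state segmentation, speeds."""

import dataclasses
import math

import numpy as np
import pytest

import septatrack as st
from septatrack.simulate import _add_gaussian
from septatrack.tracking import Spot, Track

from conftest import noisy_track_from_path


def _gauss_frame(positions, n=48, sigma=1.7, amp=400.0):
    img = np.zeros((n, n))
    for x, y in positions:
        _add_gaussian(img, x, y, sigma, amp)
    return img


class TestDetection:
    def test_false_positives_rare_on_pure_noise(self):
        fp = 0
        for s in range(100):
            frame = np.random.default_rng(s).normal(20, 3, (48, 48))
            fp += len(st.detect_spots(frame, snr_threshold=5.0))
        assert fp <= 1

    def test_single_spot_localized_subpixel(self):
        frame = _gauss_frame([(30.3, 20.7)])
        frame += np.random.default_rng(0).normal(0, 0.5, frame.shape)
        spots = st.detect_spots(frame, snr_threshold=3.0)
        assert len(spots) == 1
        assert math.hypot(spots[0].x - 30.3, spots[0].y - 20.7) < 0.5

    def test_two_separated_spots_both_found(self):
        frame = _gauss_frame([(15.0, 15.0), (25.0, 15.0)])
        frame += np.random.default_rng(1).normal(0, 0.5, frame.shape)
        spots = st.detect_spots(frame, snr_threshold=3.0)
        assert len(spots) == 2


class TestLinking:
    def _drifting_spots(self, n_frames, step_deg=1.0, theta0=0.0):
        out = []
        for f in range(n_frames):
            s = Spot(frame=f, x=0, y=0, amplitude=1.0,
                     theta=(theta0 + f * step_deg) % 360.0)
            out.append([s])
        return out

    def test_single_drifting_spot_one_full_track(self):
        tracks = st.link_spots(self._drifting_spots(30), min_len=10)
        assert len(tracks) == 1
        assert len(tracks[0]) == 30

    def test_gap_within_limit_is_closed(self):
        spots = self._drifting_spots(30)
        for f in range(10, 15):   # 5 missing frames
            spots[f] = []
        tracks = st.link_spots(spots, min_len=10)
        assert len(tracks) == 1
        assert len(tracks[0]) == 25

    def test_gap_beyond_limit_splits_track(self):
        spots = self._drifting_spots(40)
        for f in range(15, 21):   # 6 missing frames: beyond the 5-frame gap
            spots[f] = []
        tracks = st.link_spots(spots, min_len=10)
        assert len(tracks) == 2

    def test_short_tracks_discarded(self):
        tracks = st.link_spots(self._drifting_spots(9), min_len=10)
        assert tracks == []

    def test_arc_metric_wraps_at_360(self):
        spots = self._drifting_spots(20, step_deg=2.0, theta0=350.0)
        tracks = st.link_spots(spots, min_len=10)
        assert len(tracks) == 1

    def test_noiseless_partition_matches_ground_truth(self, untreated):
        """Two well-separated molecules come back as exactly two tracks."""
        rng = np.random.default_rng(8)
        frames = []
        for f in range(40):
            frames.append([
                Spot(frame=f, x=0, y=0, amplitude=1.0,
                     theta=(f * 1.5) % 360.0),
                Spot(frame=f, x=0, y=0, amplitude=1.0,
                     theta=(180.0 + f * 1.5) % 360.0)])
        tracks = st.link_spots(frames, min_len=10)
        assert len(tracks) == 2
        assert all(len(t) == 40 for t in tracks)


class TestSegmentation:
    def test_immobile_track_single_censored_segment(self):
        rng = np.random.default_rng(0)
        theta = 40.0 + np.degrees(rng.normal(0, 10, 60) / 450.0)
        tr = Track(id=0, mode="ring", spots=[
            Spot(frame=f, x=0, y=0, amplitude=1.0, theta=float(t))
            for f, t in enumerate(theta)])
        segs = st.segment_track_states(tr, 1.0, 450.0)
        assert len(segs) == 1
        assert segs[0].state == "immobile"
        assert segs[0].censored

    def test_direction_flip_boundary_located(self):
        rng = np.random.default_rng(1)
        t = np.arange(80.0)
        arc = np.where(t <= 40, 13.4 * t, 13.4 * 80 - 13.4 * t)
        arc = arc + rng.normal(0, 15, 80)
        tr = Track(id=0, mode="ring", spots=[
            Spot(frame=int(f), x=0, y=0, amplitude=1.0,
                 theta=float(np.degrees(a / 450.0)))
            for f, a in zip(t, arc)])
        segs = st.segment_track_states(tr, 1.0, 450.0)
        proc = [s for s in segs if s.state == "processive"]
        assert len(proc) == 2
        assert proc[0].end_cause == "direction_flip"
        assert proc[0].end_time == pytest.approx(40, abs=3)
        assert proc[0].speed * proc[1].speed < 0

    def test_frame_level_state_accuracy(self, untreated):
        """At least 80% of frames get the ground-truth state label."""
        rng = np.random.default_rng(2)
        correct = total = 0
        for i in range(60):
            path = st.sample_state_path(untreated, 120, rng=rng)
            if len(path) < 10:
                continue
            tr = noisy_track_from_path(path, untreated, rng, track_id=i)
            segs = st.segment_track_states(tr, 1.0, untreated.ring_radius)
            est = np.empty(len(path), dtype=object)
            for s in segs:
                i0, i1 = int(round(s.start_time)), int(round(s.end_time))
                est[i0:i1 + 1] = s.state
            correct += (est == path.state_labels).sum()
            total += len(path)
        assert correct / total >= 0.80

    def test_segments_tile_track(self, untreated):
        rng = np.random.default_rng(3)
        for i in range(20):
            path = st.sample_state_path(untreated, 120, rng=rng)
            if len(path) < 10:
                continue
            tr = noisy_track_from_path(path, untreated, rng, track_id=i)
            segs = st.segment_track_states(tr, 1.0, untreated.ring_radius)
            assert segs[0].start_time == tr.spots[0].frame
            assert segs[-1].end_time == tr.spots[-1].frame
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end_time == b.start_time
            assert sum(s.duration for s in segs) == pytest.approx(
                tr.spots[-1].frame - tr.spots[0].frame)


class TestSpeed:
    def test_exact_slope(self):
        assert st.segment_speed([0, 1, 2], [0, 13.4, 26.8]) == \
            pytest.approx(13.4)

    def test_static_speed_zero(self):
        assert st.segment_speed([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_degrees_per_second_conversion(self):
        # 1 deg/s on a 450 nm ring is 450*pi/180 nm/s
        t = np.arange(10.0)
        arc = np.radians(t) * 450.0
        assert st.segment_speed(t, arc) == pytest.approx(7.854, abs=1e-3)

    def test_speed_estimator_unbiased_and_rotation_invariant(self, untreated):
        """Relative error under 2% over 500 segments; exact under rotation."""
        rng = np.random.default_rng(4)
        rel = []
        for _ in range(500):
            v = rng.uniform(5, 50) * rng.choice([-1, 1])
            n = rng.integers(10, 40)
            t = np.arange(n, dtype=float)
            arc = v * t + rng.normal(0, 15, n)
            est = st.segment_speed(t, arc)
            rel.append((est - v) / v)
            # origin rotation adds a constant arc offset
            assert st.segment_speed(t, arc + 450.0 * np.pi / 3) == \
                pytest.approx(est)
        assert abs(np.mean(rel)) < 0.02


class TestOffAxis:
    def _linear_track(self, xy, track_id=0):
        return Track(id=track_id, mode="linear", spots=[
            Spot(frame=f, x=float(x), y=float(y), amplitude=1.0)
            for f, (x, y) in enumerate(xy)])

    def test_collinear_track_zero_median(self):
        xy = np.column_stack([np.arange(20.0), 2.0 + 0.5 * np.arange(20.0)])
        d, med = st.off_axis_displacements([self._linear_track(xy)],
                                           pixel_size=65.0)
        assert med == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_jitter_median_is_half_normal(self):
        # median |N(0, 10 nm)| = 10 * 0.6745 nm
        rng = np.random.default_rng(5)
        tracks = []
        for i in range(500):
            x = np.arange(20.0)
            y = rng.normal(0, 10.0 / 65.0, 20)
            tracks.append(self._linear_track(np.column_stack([x, y]), i))
        d, med = st.off_axis_displacements(tracks, pixel_size=65.0)
        assert med == pytest.approx(6.745, rel=0.10)

    def test_identical_conditions_agree_within_2nm(self):
        rng = np.random.default_rng(6)
        meds = []
        for _ in range(2):
            tracks = []
            for i in range(300):
                x = np.arange(20.0)
                y = rng.normal(0, 10.0 / 65.0, 20)
                tracks.append(self._linear_track(np.column_stack([x, y]), i))
            meds.append(st.off_axis_displacements(tracks, 65.0)[1])
        assert abs(meds[0] - meds[1]) < 2.0

    def test_short_tracks_skipped(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0]])
        d, med = st.off_axis_displacements([self._linear_track(xy)], 65.0)
        assert len(d) == 0 and math.isnan(med)
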