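"""Speed computation, bout detection and epoch segmentation."""

import numpy as np
import pytest

import boutlab as bl
from boutlab.segmentation import (
    SegmentationParams,
    compute_speed,
    detect_bouts,
    segment_epoch,
)
from conftest import gaussian_pulse_speed


class TestComputeSpeed:
    def test_stationary_fish_has_zero_speed(self, make_speed_track):
        track, _ = make_speed_track(np.zeros(50))
        assert np.all(compute_speed(track, 1) == 0.0)

    def test_constant_advance_gives_constant_speed(self, meta):
        """0.06 mm/frame at 166 Hz is 9.96 mm/s at every interior frame."""
        n, fr = 200, 166.0
        tr = bl.TrackSeries("e0", np.arange(n) / fr, 0.06 * np.arange(n),
                            np.zeros(n), np.zeros(n), fr)
        speed = compute_speed(tr, 1)
        np.testing.assert_allclose(speed[1:-1], 0.06 * 166.0, rtol=1e-12)

    def test_matches_brute_force_finite_differences(self, rng, meta):
        """Random-walk track equals an independent per-frame recomputation."""
        n, fr = 300, 166.0
        x = np.cumsum(rng.normal(0, 0.02, n))
        z = np.cumsum(rng.normal(0, 0.02, n))
        tr = bl.TrackSeries("e0", np.arange(n) / fr, x, z, np.zeros(n), fr)
        speed = compute_speed(tr, 1)
        # brute force, one frame at a time
        expected = np.empty(n)
        for i in range(n):
            if i == 0:
                dx, dz = x[1] - x[0], z[1] - z[0]
            elif i == n - 1:
                dx, dz = x[-1] - x[-2], z[-1] - z[-2]
            else:
                dx, dz = (x[i + 1] - x[i - 1]) / 2, (z[i + 1] - z[i - 1]) / 2
            expected[i] = fr * np.sqrt(dx * dx + dz * dz)
        np.testing.assert_allclose(speed, expected, rtol=1e-12)

    def test_smoothing_preserves_length_and_positivity(self, rng, meta):
        n, fr = 300, 166.0
        x = np.cumsum(rng.normal(0, 0.02, n))
        tr = bl.TrackSeries("e0", np.arange(n) / fr, x, np.zeros(n), np.zeros(n), fr)
        s3 = compute_speed(tr, 3)
        assert len(s3) == n and np.all(s3 >= 0)
        # interior smoothing equals the plain 3-frame mean of raw speed
        raw = compute_speed(tr, 1)
        np.testing.assert_allclose(s3[1:-1], (raw[:-2] + raw[1:-1] + raw[2:]) / 3, atol=1e-9)

    def test_rejects_bad_windows_and_short_epochs(self, make_speed_track):
        track, _ = make_speed_track(np.zeros(10))
        with pytest.raises(ValueError):
            compute_speed(track, 2)  # even
        with pytest.raises(ValueError):
            compute_speed(track, 11)  # longer than epoch


class TestDetectBouts:
    fr = 166.0

    def test_all_subthreshold_means_no_bouts(self):
        runs = detect_bouts(np.full(1000, 4.9), self.fr)
        assert len(runs) == 0

    def test_single_pulse_single_peak(self):
        speed = gaussian_pulse_speed(400, 200, 12.0, 15.0)
        runs = detect_bouts(speed, self.fr)
        assert len(runs) == 1
        assert runs.peak[0] == 200

    def test_merge_gap_semantics(self):
        """A 20 ms sub-threshold dip merges at merge_gap=30 ms, splits at 0."""
        fr = 200.0  # 20 ms = 4 frames exactly
        speed = np.zeros(300)
        speed[100:120] = 12.0
        speed[124:144] = 12.0  # 4-frame gap = 20 ms
        merged = detect_bouts(speed, fr, merge_gap=0.03)
        split = detect_bouts(speed, fr, merge_gap=0.0)
        assert len(merged) == 1 and len(split) == 2

    def test_min_duration_discards_blips(self):
        speed = np.zeros(300)
        speed[100:102] = 12.0  # 2 frames < 3-frame minimum
        speed[200:220] = 12.0
        runs = detect_bouts(speed, self.fr, min_duration=0.018)
        assert len(runs) == 1 and runs.start[0] == 200

    def test_tie_broken_to_earliest_frame(self):
        speed = np.zeros(100)
        speed[40:50] = 10.0  # flat top: every frame ties
        runs = detect_bouts(speed, self.fr)
        assert runs.peak[0] == 40

    def test_agrees_with_run_length_oracle(self, rng):
        """Detected runs equal a brute-force scan on random traces."""
        for _ in range(100):
            speed = rng.uniform(0, 12, size=rng.integers(20, 200))
            runs = detect_bouts(speed, self.fr, min_duration=0.0, merge_gap=0.0)
            # oracle: explicit scan
            expected = []
            in_run, s = False, 0
            for i, v in enumerate(speed):
                if v > 5.0 and not in_run:
                    in_run, s = True, i
                elif v <= 5.0 and in_run:
                    expected.append((s, i))
                    in_run = False
            if in_run:
                expected.append((s, len(speed)))
            assert list(zip(runs.start, runs.end)) == expected
            for (s, e), pk in zip(expected, runs.peak):
                assert pk == s + int(np.argmax(speed[s:e]))

    def test_bout_count_non_increasing_in_merge_gap(self, rng):
        """Merging monotonicity: larger gaps can only merge, never split."""
        speed = np.zeros(3000)
        pos = 50
        while pos < 2800:
            w = rng.integers(3, 30)
            speed[pos : pos + w] = rng.uniform(6, 15)
            pos += w + rng.integers(1, 40)
        counts = [
            len(detect_bouts(speed, self.fr, merge_gap=g))
            for g in [0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]
        ]
        assert counts == sorted(counts, reverse=True)


class TestSegmentEpoch:
    def test_single_bout_epoch(self, make_speed_track):
        fr = 200.0
        speed = gaussian_pulse_speed(400, 200, 12.0, 10.0)
        track, meta = make_speed_track(speed, frame_rate=fr)
        bouts, ibis = segment_epoch(track, SegmentationParams(), meta)
        assert len(bouts) == 1 and len(ibis) == 0
        b = bouts[0]
        assert len(b.window_t) == int(0.25 * fr) + int(0.20 * fr) + 1

    def test_window_aligned_on_peak(self):
        """Max of window_speed occurs at relative time 0 for every bout."""
        p = bl.preset("dark_strategy", seed=11, duration_h=0.1)
        tracks, meta, _ = bl.generate_recording(p)
        bouts, _ = bl.segment_recording(tracks, meta)
        assert bouts
        for b in bouts:
            pk = np.searchsorted(b.window_t, 0.0)
            assert np.argmax(b.window_speed) == pk

    def test_truncated_head_bout_excluded(self, make_speed_track):
        """A bout peaking < 250 ms after epoch start cannot be windowed."""
        fr = 200.0
        speed = gaussian_pulse_speed(500, 30, 12.0, 8.0)  # peak at 150 ms
        speed += gaussian_pulse_speed(500, 300, 12.0, 8.0)
        track, meta = make_speed_track(speed, frame_rate=fr)
        bouts, ibis = segment_epoch(track, SegmentationParams(), meta)
        assert len(bouts) == 1 and bouts[0].peak_index == 300
        assert len(ibis) == 0  # no IBI across the truncated bout

    def test_bout_and_ibi_counts_link(self, dark_run):
        """Per epoch: n_ibis = n_bouts - 1, every IBI links two bouts."""
        _, _, _, bdf, idf = dark_run
        assert len(idf) == len(bdf) - 1
        assert (idf["following_bout"].to_numpy() == idf["preceding_bout"].to_numpy() + 1).all()
        assert (idf["duration_s"] > 0).all()

    def test_ibi_durations_match_generator_log(self, dark_run):
        """Measured IBI durations equal the logged run-edge gaps (2 frames)."""
        tracks, meta, log, bdf, idf = dark_run
        n = min(len(idf), len(log.ibis))
        assert n > 100
        measured = idf["duration_s"].to_numpy()[:n]
        truth = log.ibis["duration_s"].to_numpy()[:n]
        assert np.median(np.abs(measured - truth)) < 2.0 / meta.frame_rate


class TestDetectionQuality:
    def test_high_snr_recall_and_precision(self):
        """Recall and precision exceed 0.99 for clearly detectable bouts.

        Conditions: peak speeds at least twice the threshold, inter-bout
        gaps of 300 ms or more, >= 500 bouts, fixed seed.
        """
        p = bl.preset(
            "dark_strategy", seed=5, duration_h=0.5,
            ibi_min=0.35, min_peak_speed=10.0,
        )
        p.dark.peak_speed_mean = 14.0
        p.dark.peak_speed_cv = 0.2
        tracks, meta, log = bl.generate_recording(p)
        bouts, ibis = bl.segment_recording(tracks, meta)
        bdf = bl.bout_table(bouts, ibis)
        assert len(log.bouts) >= 500
        rep = bl.truth_vs_pipeline_report(log, bdf, min_true_peak=10.0)
        assert rep.recall >= 0.99
        assert rep.precision >= 0.99

    def test_no_false_bouts_without_noise(self):
        """With zero tracking jitter and drift noise, no spurious bouts."""
        p = bl.preset("dark_strategy", seed=6, duration_h=0.2,
                      pos_noise=0.0, drift_noise=1e-9, pitch_noise=0.0)
        tracks, meta, log = bl.generate_recording(p)
        bouts, ibis = bl.segment_recording(tracks, meta)
        bdf = bl.bout_table(bouts, ibis)
        rep = bl.truth_vs_pipeline_report(log, bdf)
        assert rep.precision == 1.0
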