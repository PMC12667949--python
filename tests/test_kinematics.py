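"""Per-bout kinematics: FWHM duration, displacement, direction, rotation."""

import numpy as np
import pytest

import boutlab as bl
from boutlab.kinematics import (
    bout_displacement,
    bout_duration_fwhm,
    bout_rotation,
    direction_at_peak,
    fwhm_from_profiles,
    rotation_from_windows,
)
from boutlab.segmentation import SegmentationParams, segment_epoch
from conftest import gaussian_pulse_speed

FR = 200.0  # 0.25*fr and 0.20*fr are whole frames: window is exactly -250..+200 ms
PRE, POST = 50, 40
W = PRE + POST + 1


def _profile(values):
    """Pad a speed fragment into a W-sample window peaking at column PRE."""
    out = np.zeros(W)
    out[: len(values)] = values
    return out


class TestFWHM:
    def test_triangular_pulse(self):
        """100 ms linear rise + 100 ms fall: half-max points sit at the
        midpoints, so FWHM equals the ramp duration exactly."""
        rise = np.linspace(0.0, 20.0, 21)  # 20 frames = 100 ms up
        fall = np.linspace(20.0, 0.0, 21)[1:]
        w = np.zeros(W)
        w[PRE - 20 : PRE + 1] = rise
        w[PRE + 1 : PRE + 21] = fall
        fwhm, censored = fwhm_from_profiles(w, FR, PRE)
        assert not censored
        assert fwhm == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("width", [5, 10, 20])
    def test_rectangular_pulse(self, width):
        """A w-frame rectangle has FWHM of w frame-periods (within one)."""
        w = np.zeros(W)
        w[PRE - width // 2 : PRE - width // 2 + width] = 10.0
        fwhm, _ = fwhm_from_profiles(w, FR, PRE)
        assert fwhm == pytest.approx(width * 1000.0 / FR, abs=1000.0 / FR)

    def test_gaussian_pulse_closed_form(self):
        """FWHM of a Gaussian of sigma 42.47 ms is 100 ms (2*sqrt(2 ln 2)*sigma)."""
        sigma_frames = 0.04247 * FR
        w = gaussian_pulse_speed(W, PRE, 12.0, sigma_frames)
        fwhm, _ = fwhm_from_profiles(w, FR, PRE)
        assert fwhm == pytest.approx(100.0, abs=2 * 1000.0 / FR)

    def test_censored_at_window_edge(self):
        """A profile that never falls below half-max is flagged censored."""
        w = np.full(W, 10.0)
        w[PRE] = 10.5
        fwhm, censored = fwhm_from_profiles(w, FR, PRE)
        assert censored
        assert fwhm == pytest.approx((W - 1) * 1000.0 / FR)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            fwhm_from_profiles(np.zeros(W), FR, PRE)

    def test_vectorized_matches_per_bout(self, rng):
        profs = np.stack([gaussian_pulse_speed(W, PRE, p, s)
                          for p, s in zip(rng.uniform(6, 15, 50), rng.uniform(3, 25, 50))])
        fv, cv = fwhm_from_profiles(profs, FR, PRE)
        for i in range(50):
            fi, ci = fwhm_from_profiles(profs[i], FR, PRE)
            assert fv[i] == fi and cv[i] == ci


class TestRotation:
    def test_constant_pitch_no_rotation(self):
        assert rotation_from_windows(np.full(W, 7.0)) == 0.0

    def test_linear_ramp_ten_deg_per_s(self, make_speed_track):
        """10 deg/s across the 450 ms window nets 4.5 deg, end to end."""
        n = 600
        speed = gaussian_pulse_speed(n, 300, 12.0, 10.0)
        pitch = 10.0 * np.arange(n) / FR
        track, meta = make_speed_track(speed, frame_rate=FR, pitch=pitch)
        bouts, _ = segment_epoch(track, SegmentationParams(), meta)
        assert len(bouts) == 1
        assert bout_rotation(bouts[0]) == pytest.approx(4.5, abs=1e-9)

    def test_generator_rotation_recovered(self, dark_run):
        """Pipeline rotations match the generator's programmed rotations to
        within twice the pitch observation noise."""
        tracks, meta, log, bdf, _ = dark_run
        rep = bl.truth_vs_pipeline_report(log, bdf)
        row = rep.table.set_index("parameter").loc["rotation_deg"]
        # rotation endpoints carry 2 independent pitch-noise samples
        p = bl.preset("dark_strategy")
        assert row["rmse"] < 2 * p.pitch_noise * np.sqrt(2)
        assert abs(row["bias"]) < 0.1


class TestDirection:
    def test_equal_rise_and_run_is_45_degrees(self):
        x = np.arange(W) * 0.01
        z = np.arange(W) * 0.01
        assert direction_at_peak(x, z, PRE) == pytest.approx(45.0)

    def test_horizontal_motion_is_zero(self):
        x = np.arange(W) * 0.01
        assert direction_at_peak(x, np.zeros(W), PRE) == pytest.approx(0.0)

    def test_leftward_swimming_same_convention(self):
        """Mirroring x leaves the vertical direction unchanged (|dx|)."""
        x = np.arange(W) * 0.01
        z = np.arange(W) * 0.005
        assert direction_at_peak(-x, z, PRE) == direction_at_peak(x, z, PRE)

    def test_vertical_mirror_flips_sign(self):
        x = np.arange(W) * 0.01
        z = np.arange(W) * 0.005
        assert direction_at_peak(x, -z, PRE) == -direction_at_peak(x, z, PRE)

    def test_stationary_peak_is_undefined(self):
        assert np.isnan(direction_at_peak(np.zeros(W), np.zeros(W), PRE))

    def test_generator_mean_direction_recovered(self):
        """Programmed 13-degree climbs recover to within 1 degree at n>=1000."""
        p = bl.preset("dark_strategy", seed=12, duration_h=0.7)
        tracks, meta, log = bl.generate_recording(p)
        bouts, ibis = bl.segment_recording(tracks, meta)
        bdf = bl.bout_table(bouts, ibis)
        assert len(bdf) >= 1000
        assert bdf["direction_deg"].mean() == pytest.approx(13.0, abs=1.0)


class TestDisplacement:
    def test_straight_run(self, make_speed_track):
        """A horizontal run covering 1.2 mm super-threshold returns 1.2 mm."""
        speed = np.zeros(300)
        speed[100:140] = 6.0  # 40 frames at 6 mm/s at 200 Hz = 1.2 mm
        track, meta = make_speed_track(speed, frame_rate=FR)
        bouts, _ = segment_epoch(track, SegmentationParams(), meta)
        assert len(bouts) == 1
        # smoothing trims about a frame from each run edge
        assert bout_displacement(bouts[0]) == pytest.approx(1.2, rel=0.1)

    def test_matches_brute_force_step_sum(self, dark_run):
        tracks, meta, log, bdf, _ = dark_run
        bouts, ibis = bl.segment_recording(tracks, meta)
        for b in bouts[:200]:
            manual = sum(
                np.sqrt((b.run_x[i + 1] - b.run_x[i]) ** 2 + (b.run_z[i + 1] - b.run_z[i]) ** 2)
                for i in range(len(b.run_x) - 1)
            )
            assert bout_displacement(b) == pytest.approx(manual, abs=1e-12)

    def test_invariant_under_horizontal_mirroring(self, make_speed_track):
        speed = gaussian_pulse_speed(400, 200, 12.0, 10.0)
        track, meta = make_speed_track(speed, frame_rate=FR)
        bouts, _ = segment_epoch(track, SegmentationParams(), meta)
        d0 = bout_displacement(bouts[0])
        track.x[:] = -track.x
        bouts2, _ = segment_epoch(track, SegmentationParams(), meta)
        assert bout_displacement(bouts2[0]) == pytest.approx(d0, abs=1e-12)


class TestIBIDrift:
    def test_no_pitch_change_zero_drift(self, make_speed_track):
        speed = np.zeros(800)
        speed[:] += gaussian_pulse_speed(800, 200, 12.0, 8.0)
        speed += gaussian_pulse_speed(800, 600, 12.0, 8.0)
        track, meta = make_speed_track(speed, frame_rate=FR)
        _, ibis = segment_epoch(track, SegmentationParams(), meta)
        assert len(ibis) == 1
        assert bl.ibi_drift(ibis[0]) == 0.0

    def test_programmed_drift_recovered(self):
        """With a deterministic -3 deg/s drift the measured IBI drift equals
        the logged accrual exactly, and averages -3 deg/s times the mean gap."""
        p = bl.preset("dark_strategy", seed=13, duration_h=0.3,
                      drift_rate=3.0, drift_noise=0.0, pitch_noise=0.0,
                      pos_noise=0.0)
        p.dark.ibi_mean = 2.0
        tracks, meta, log = bl.generate_recording(p)
        _, ibis = bl.segment_recording(tracks, meta)
        drifts = np.array([bl.ibi_drift(i) for i in ibis])
        n = min(len(drifts), len(log.ibis))
        np.testing.assert_allclose(drifts[:n], log.ibis["drift_deg"].to_numpy()[:n], atol=1e-9)
        # mean accrual over gamma(mean 2 s) gaps: about -6 deg
        assert np.mean(drifts) == pytest.approx(-3.0 * 2.0, rel=0.15)

    def test_nose_down_generator_gives_negative_median(self, dark_run):
        _, _, _, _, idf = dark_run
        assert idf["drift_deg"].median() < 0


def test_noise_free_parameters_match_ground_truth():
    """With observation noise off, every kinematic parameter matches the
    generator log tightly (durations within a frame-period, angles near
    machine precision for rotation)."""
    p = bl.preset("dark_strategy", seed=14, duration_h=0.2,
                  pos_noise=0.0, pitch_noise=0.0, drift_noise=0.0)
    tracks, meta, log = bl.generate_recording(p)
    bouts, ibis = bl.segment_recording(tracks, meta)
    bdf = bl.bout_table(bouts, ibis)
    rep = bl.truth_vs_pipeline_report(log, bdf)
    t = rep.table.set_index("parameter")
    frame_ms = 1000.0 / meta.frame_rate
    assert t.loc["fwhm_ms", "rmse"] <= 2 * frame_ms
    assert t.loc["rotation_deg", "rmse"] < 1e-6
    assert t.loc["preceding_drift_deg", "rmse"] < 1e-6
    assert t.loc["direction_deg", "rmse"] < 1.0
    assert t.loc["peak_speed", "rmse"] < 0.5
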