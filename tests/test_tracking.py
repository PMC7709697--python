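"""Tracking pipeline: calibration, stitching, speed, drift decomposition."""

import numpy as np
import pandas as pd
import pytest

from jellyswim import (
    DisplacementSeries,
    SyntheticTrackSpec,
    TrackSeries,
    calibrate,
    calibrate_series,
    decompose_horizontal,
    gen_track,
    measured_frequency,
    stitch_displacement,
    vertical_speed,
)
from jellyswim.tracking import CalibrationGapError, UnstitchableGapError


def frame_df(rows):
    return pd.DataFrame(rows, columns=["frame", "time_s", "label", "x_px", "y_px"])


def test_two_adjacent_markers_100px_apart():
    markers = frame_df([
        (0, 0.0, "marker_red_0", 500.0, 800.0),
        (0, 0.0, "marker_yellow_1", 500.0, 700.0),
    ])
    cal = calibrate(markers, marker_spacing=30.5)
    assert cal.cm_per_px == pytest.approx(0.305)


def test_three_equally_spaced_markers_spanning_200px():
    markers = frame_df([
        (0, 0.0, "marker_red_0", 500.0, 900.0),
        (0, 0.0, "marker_yellow_1", 500.0, 800.0),
        (0, 0.0, "marker_red_2", 500.0, 700.0),
    ])
    cal = calibrate(markers, marker_spacing=30.5)
    assert cal.cm_per_px == pytest.approx(61.0 / 200.0)


def test_single_marker_cannot_calibrate():
    with pytest.raises(CalibrationGapError):
        calibrate(frame_df([(0, 0.0, "marker_red_0", 500.0, 900.0)]))


def test_calibration_recovered_under_pixel_noise():
    spec = SyntheticTrackSpec(true_speed=3.0, duration=20, seed=11)
    tracks, truth = gen_track(spec)
    cal = calibrate_series(tracks)
    rel = np.abs(cal.cm_per_px.to_numpy() - truth.cm_per_px) / truth.cm_per_px
    assert np.median(rel) < 0.005


def test_static_housing_moving_camera_gives_zero_displacement():
    """Camera motion is shared by housing and markers, so marker-relative
    displacement cancels it."""
    spec = SyntheticTrackSpec(true_speed=0.0, duration=10, pixel_noise_sd=0.0,
                              quantize=False, horiz_amp=0.0,
                              camera_drift_amp_px=60.0)
    tracks, _ = gen_track(spec)
    disp = stitch_displacement(tracks, calibrate_series(tracks))
    assert np.max(np.abs(disp.vertical_cm)) < 1e-9
    assert np.max(np.abs(disp.horizontal_cm)) < 1e-9


def test_constant_ascent_recovered_within_error():
    spec = SyntheticTrackSpec(true_speed=5.0, duration=20, seed=7)
    tracks, truth = gen_track(spec)
    disp = stitch_displacement(tracks, calibrate_series(tracks))
    speed, err = vertical_speed(disp)
    assert err > 0
    assert abs(speed - truth.speed) < err
    # displacement is linear in time: residual from the fitted line is small
    fit = np.polyfit(disp.time, disp.vertical_cm, 1)
    assert fit[0] == pytest.approx(truth.speed, abs=0.1)


def test_red_only_matches_full_stitch_within_error():
    """Mirrors the overlap-accuracy check: tracks stitched from one marker
    color agree with the red+yellow stitch."""
    spec = SyntheticTrackSpec(true_speed=4.0, duration=15, seed=5)
    tracks, _ = gen_track(spec)
    disp_full = stitch_displacement(tracks, calibrate_series(tracks))
    red = tracks.data[
        (tracks.data["label"] == "housing")
        | tracks.data["label"].str.startswith("marker_red")
    ]
    tracks_red = TrackSeries(data=red, frame_rate=tracks.frame_rate)
    disp_red = stitch_displacement(tracks_red, calibrate_series(tracks_red))
    v_full, e_full = vertical_speed(disp_full)
    v_red, e_red = vertical_speed(disp_red)
    assert abs(v_full - v_red) < e_full + e_red
    # noise-free: the two stitches agree exactly
    clean_spec = SyntheticTrackSpec(true_speed=4.0, duration=10,
                                    pixel_noise_sd=0.0, quantize=False)
    clean, _ = gen_track(clean_spec)
    d1 = stitch_displacement(clean, calibrate_series(clean))
    red_c = clean.data[
        (clean.data["label"] == "housing")
        | clean.data["label"].str.startswith("marker_red")
    ]
    tr_red = TrackSeries(data=red_c, frame_rate=clean.frame_rate)
    d2 = stitch_displacement(tr_red, calibrate_series(tr_red))
    np.testing.assert_allclose(d1.vertical_cm, d2.vertical_cm, atol=1e-8)


def test_unstitchable_without_markers():
    spec = SyntheticTrackSpec(true_speed=2.0, duration=5, pixel_noise_sd=0.0,
                              quantize=False)
    tracks, _ = gen_track(spec)
    housing_only = tracks.data[tracks.data["label"] == "housing"]
    with pytest.raises(UnstitchableGapError):
        stitch_displacement(
            TrackSeries(data=housing_only, frame_rate=30.0),
            calibrate_series(tracks),
        )


def test_vertical_speed_finite_difference_definition():
    disp = DisplacementSeries(
        time=np.array([0.0, 1.0, 2.0, 3.0]),
        vertical_cm=np.array([0.0, 1.0, 2.0, 3.0]),
        horizontal_cm=np.zeros(4),
        err_cm=np.full(4, 0.1),
    )
    speed, err = vertical_speed(disp)
    assert speed == pytest.approx(1.0)
    assert err > 0
    flat = DisplacementSeries(time=np.arange(4.0), vertical_cm=np.zeros(4),
                              horizontal_cm=np.zeros(4), err_cm=np.full(4, 0.1))
    assert vertical_speed(flat)[0] == 0.0
    with pytest.raises(ValueError):
        vertical_speed(DisplacementSeries(time=np.array([0.0]),
                                          vertical_cm=np.array([0.0]),
                                          horizontal_cm=np.array([0.0]),
                                          err_cm=np.array([0.1])))


def test_scale_invariance_of_displacement():
    """Scaling all pixel coordinates by c and the scene scale by 1/c leaves
    centimetre displacements unchanged."""
    spec1 = SyntheticTrackSpec(true_speed=3.0, duration=10, pixel_noise_sd=0.0,
                               quantize=False, cm_per_px=0.3)
    spec2 = SyntheticTrackSpec(true_speed=3.0, duration=10, pixel_noise_sd=0.0,
                               quantize=False, cm_per_px=0.15)
    d1 = stitch_displacement(*(lambda t: (t, calibrate_series(t)))(gen_track(spec1)[0]))
    d2 = stitch_displacement(*(lambda t: (t, calibrate_series(t)))(gen_track(spec2)[0]))
    np.testing.assert_allclose(d1.vertical_cm, d2.vertical_cm, atol=1e-8)


def test_decompose_sine_plus_drift():
    t = np.arange(0, 20, 1 / 30)
    horiz = 2.0 * np.sin(2 * np.pi * t / 4.0) + 0.3 * t + 1.0
    disp = DisplacementSeries(time=t, vertical_cm=np.zeros_like(t),
                              horizontal_cm=horiz,
                              err_cm=np.full_like(t, 0.1))
    detrended, amp, period = decompose_horizontal(disp)
    assert amp == pytest.approx(2.0, rel=0.05)
    assert period == pytest.approx(4.0, rel=0.05)
    assert len(detrended) == len(t)


def test_decompose_zero_and_linearity():
    t = np.arange(0, 12, 1 / 30)
    flat = DisplacementSeries(time=t, vertical_cm=np.zeros_like(t),
                              horizontal_cm=np.zeros_like(t),
                              err_cm=np.full_like(t, 0.1))
    with pytest.warns(UserWarning):
        _, amp, _ = decompose_horizontal(flat)
    assert amp == 0.0
    one = DisplacementSeries(time=t, vertical_cm=np.zeros_like(t),
                             horizontal_cm=np.sin(2 * np.pi * t / 3.0),
                             err_cm=np.full_like(t, 0.1))
    two = DisplacementSeries(time=t, vertical_cm=np.zeros_like(t),
                             horizontal_cm=2 * np.sin(2 * np.pi * t / 3.0),
                             err_cm=np.full_like(t, 0.1))
    assert decompose_horizontal(two)[1] == pytest.approx(
        2 * decompose_horizontal(one)[1]
    )


def test_short_record_warns_without_period():
    t = np.arange(0, 2, 1 / 30)
    disp = DisplacementSeries(time=t, vertical_cm=np.zeros_like(t),
                              horizontal_cm=2.0 * np.sin(2 * np.pi * t / 40.0),
                              err_cm=np.full_like(t, 0.1))
    with pytest.warns(UserWarning):
        _, amp, period = decompose_horizontal(disp)
    assert np.isnan(period)
    assert amp > 0


def test_measured_frequency_counting():
    assert measured_frequency([1, 3, 5, 7, 9], 10.0) == pytest.approx(0.50)
    assert measured_frequency([], 10.0) == 0.0
    with pytest.raises(ValueError):
        measured_frequency([1.0], 0.0)


def test_track_series_invariants():
    bad_time = frame_df([(0, 0.5, "housing", 10.0, 10.0)])
    with pytest.raises(ValueError):
        TrackSeries(data=bad_time, frame_rate=30.0)
    out_of_frame = frame_df([(0, 0.0, "housing", -5.0, 10.0)])
    with pytest.raises(ValueError):
        TrackSeries(data=out_of_frame, frame_rate=30.0)
    dup = frame_df([(0, 0.0, "housing", 10.0, 10.0),
                    (0, 0.0, "housing", 11.0, 10.0)])
    with pytest.raises(ValueError):
        TrackSeries(data=dup, frame_rate=30.0)
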