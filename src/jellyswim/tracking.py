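"""Field-video analysis: from labeled centroid tracks to calibrated
displacement, mean vertical speed with propagated pixel error, and pulse
frequency counting.

The raw material is a centroid time series for the swim-controller housing
and for rope markers of known 30.5 cm spacing. Marker labels carry their
rope index (`marker_red_4` sits 4 spacings above `marker_red_0`; red
markers occupy even indices, yellow odd). Expressing the housing position
relative to the markers removes camera motion; the marker spacing converts
pixels to centimetres. Screen y grows downward, so ascent is converted to
positive vertical displacement.

Centroids are assumed accurate to about one pixel; that uncertainty, plus
integer-pixel quantization, is propagated in quadrature through the scale
conversion into per-frame displacement errors and a mean-speed error.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TrackSeries",
    "Calibration",
    "DisplacementSeries",
    "CalibrationGapError",
    "UnstitchableGapError",
    "calibrate",
    "calibrate_series",
    "stitch_displacement",
    "vertical_speed",
    "decompose_horizontal",
    "measured_frequency",
]

# centroid uncertainty model: ~1 px accuracy plus uniform +-0.5 px rounding
CENTROID_ERR_PX = 1.0
_QUANT_VAR = 1.0 / 12.0
_SIGMA_PX = math.sqrt(CENTROID_ERR_PX**2 + _QUANT_VAR)

_MARKER_RE = re.compile(r"^marker_(red|yellow)_(\d+)$")

TRACK_COLUMNS = ["frame", "time_s", "label", "x_px", "y_px"]


class CalibrationGapError(ValueError):
    """Fewer than two markers visible: no scale in this frame."""


class UnstitchableGapError(ValueError):
    """A frame without any marker: housing position cannot be anchored."""


@dataclass(frozen=True)
class TrackSeries:
    """Labeled centroid tracks at a fixed frame rate.

    data columns: frame, time_s, label, x_px, y_px. Labels are 'housing'
    or 'marker_<color>_<rope index>'.
    """

    data: pd.DataFrame
    frame_rate: float = 30.0
    frame_width: int = 1920
    frame_height: int = 1080

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"track data missing columns: {sorted(missing)}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.data.duplicated(subset=["frame", "label"]).any():
            raise ValueError("duplicate (frame, label) rows")
        t_expect = self.data["frame"] / self.frame_rate
        if not np.allclose(self.data["time_s"], t_expect, atol=1e-6):
            raise ValueError("time_s must equal frame / frame_rate")
        x, y = self.data["x_px"], self.data["y_px"]
        if ((x < 0) | (x > self.frame_width) | (y < 0) | (y > self.frame_height)).any():
            raise ValueError("pixel coordinates outside frame bounds")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TrackSeries":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.data[TRACK_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimetre scale, per frame or global.

    cm_per_px is a scalar or a pandas Series indexed by frame number;
    inherited_frames lists frames whose scale was borrowed from the nearest
    calibrated frame because fewer than two markers were visible.
    """

    cm_per_px: object
    marker_spacing: float = 30.5
    inherited_frames: tuple = ()

    def __post_init__(self) -> None:
        vals = np.atleast_1d(np.asarray(self.cm_per_px, dtype=float))
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("cm_per_px must be positive and finite")

    def scale_at(self, frame: int) -> float:
        if np.isscalar(self.cm_per_px):
            return float(self.cm_per_px)
        return float(self.cm_per_px.loc[frame])


@dataclass(frozen=True)
class DisplacementSeries:
    """Calibrated displacement relative to the first frame (ascent > 0)."""

    time: np.ndarray
    vertical_cm: np.ndarray
    horizontal_cm: np.ndarray
    err_cm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "vertical_cm": self.vertical_cm,
                "horizontal_cm": self.horizontal_cm,
                "err_cm": self.err_cm,
            }
        )


def _parse_markers(frame_df: pd.DataFrame) -> pd.DataFrame:
    m = frame_df["label"].str.extract(_MARKER_RE)
    out = frame_df.assign(color=m[0], index=pd.to_numeric(m[1]))
    return out.dropna(subset=["color"]).astype({"index": int})


def _split_tracks(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Housing rows and parsed marker rows, label metadata resolved once."""
    labels = data["label"].astype(str)
    meta = labels.drop_duplicates().to_frame(name="label")
    ext = meta["label"].str.extract(_MARKER_RE)
    meta["color"] = ext[0]
    meta["index"] = pd.to_numeric(ext[1])
    merged = data.merge(meta, on="label", how="left")
    housing = merged[merged["label"] == "housing"]
    markers = merged.dropna(subset=["color"]).astype({"index": int})
    return housing, markers


def calibrate(markers: pd.DataFrame, marker_spacing: float = 30.5) -> Calibration:
    """Scale for one frame from its visible rope markers.

    cm_per_px = spacing * (gaps between outermost markers) / pixel distance.
    Raises CalibrationGapError with fewer than two distinct markers.
    """
    mk = _parse_markers(markers)
    if mk["index"].nunique() < 2:
        raise CalibrationGapError(
            "need at least two distinct markers to calibrate a frame"
        )
    lo = mk.loc[mk["index"].idxmin()]
    hi = mk.loc[mk["index"].idxmax()]
    gaps = int(hi["index"] - lo["index"])
    dist = math.hypot(hi["x_px"] - lo["x_px"], hi["y_px"] - lo["y_px"])
    if dist <= 0:
        raise CalibrationGapError("outermost markers coincide in pixel space")
    return Calibration(cm_per_px=marker_spacing * gaps / dist,
                       marker_spacing=marker_spacing)


def _outermost(markers: pd.DataFrame) -> pd.DataFrame:
    """Per frame: coordinates of the lowest- and highest-index markers, the
    gap count between them, their pixel span, and the rope axis unit vector
    (NaN where fewer than two distinct markers are visible)."""
    g = markers.groupby("frame")["index"]
    lo = markers.loc[g.idxmin()].set_index("frame")
    hi = markers.loc[g.idxmax()].set_index("frame")
    out = pd.DataFrame(index=lo.index)
    out["gaps"] = hi["index"] - lo["index"]
    vx = hi["x_px"] - lo["x_px"]
    vy = hi["y_px"] - lo["y_px"]
    out["span"] = np.hypot(vx, vy)
    ok = (out["gaps"] > 0) & (out["span"] > 0)
    out["ax"] = np.where(ok, vx / out["span"], np.nan)
    out["ay"] = np.where(ok, vy / out["span"], np.nan)
    out.loc[~ok, ["span", "gaps"]] = np.nan
    return out


def calibrate_series(tracks: TrackSeries,
                     marker_spacing: float = 30.5) -> Calibration:
    """Per-frame calibration; frames with <2 markers inherit the nearest
    calibrated frame's scale and are flagged."""
    frames = np.sort(tracks.data["frame"].unique())
    _, markers = _split_tracks(tracks.data)
    if markers.empty:
        raise CalibrationGapError("no frame contains two markers")
    outer = _outermost(markers).reindex(frames)
    scales = marker_spacing * outer["gaps"] / outer["span"]
    gaps = [int(f) for f in frames[scales.isna().to_numpy()]]
    if scales.isna().all():
        raise CalibrationGapError("no frame contains two markers")
    if gaps:
        # nearest calibrated frame (ffill/bfill on frame order)
        scales = scales.interpolate(method="nearest").ffill().bfill()
    return Calibration(cm_per_px=scales, marker_spacing=marker_spacing,
                       inherited_frames=tuple(gaps))


def stitch_displacement(tracks: TrackSeries, cal: Calibration) -> DisplacementSeries:
    """Housing displacement in the rope-marker frame, in centimetres.

    Per frame the housing position is anchored to every visible marker
    (rope index times spacing plus the pixel offset along the rope axis,
    scaled). Red and yellow estimates are averaged where both exist and
    their disagreement is folded into the error. Camera motion cancels
    because both housing and markers share it. The series is zeroed at the
    first frame.
    """
    housing, markers = _split_tracks(tracks.data)
    if housing.empty:
        raise ValueError("housing track is required")
    frames = np.sort(housing["frame"].unique())
    per_frame_markers = markers.groupby("frame").size().reindex(frames)
    if per_frame_markers.isna().any():
        bad = int(frames[per_frame_markers.isna().to_numpy()][0])
        raise UnstitchableGapError(
            f"frame {bad}: no marker visible, housing cannot be anchored"
        )

    # rope axis per frame from the outermost marker pair; frames with a
    # single marker inherit the nearest resolved axis
    outer = _outermost(markers).reindex(frames)
    if outer["ax"].isna().all():
        raise UnstitchableGapError("no frame with two markers fixes the rope axis")
    axes = outer[["ax", "ay", "span"]].ffill().bfill()

    spacing = cal.marker_spacing
    if np.isscalar(cal.cm_per_px):
        scale = pd.Series(float(cal.cm_per_px), index=frames)
    else:
        scale = cal.cm_per_px.reindex(frames).ffill().bfill()

    h_idx = housing.set_index("frame").reindex(frames)
    mk = markers.merge(
        pd.DataFrame({
            "frame": frames,
            "hx": h_idx["x_px"].to_numpy(),
            "hy": h_idx["y_px"].to_numpy(),
            "axx": axes["ax"].to_numpy(),
            "axy": axes["ay"].to_numpy(),
            "scale": scale.to_numpy(),
        }),
        on="frame",
    )
    dx = mk["hx"] - mk["x_px"]
    dy = mk["hy"] - mk["y_px"]
    mk["along"] = dx * mk["axx"] + dy * mk["axy"]
    mk["perp"] = dx * mk["axy"] - dy * mk["axx"]
    mk["height"] = mk["index"] * spacing + mk["along"] * mk["scale"]
    mk["horiz"] = mk["perp"] * mk["scale"]
    mk["abs_along"] = mk["along"].abs()

    by_color = mk.groupby(["frame", "color"], observed=True)["height"].mean().unstack("color")
    vert = by_color.mean(axis=1).reindex(frames)
    if by_color.shape[1] == 2:
        disagreement = (by_color.iloc[:, 0] - by_color.iloc[:, 1]).abs().fillna(0.0)
    else:
        disagreement = pd.Series(0.0, index=by_color.index)
    disagreement = disagreement.reindex(frames).fillna(0.0)

    by_frame = mk.groupby("frame")
    horiz = by_frame["horiz"].mean().reindex(frames)
    m = by_frame.size().reindex(frames)
    offset_cm = by_frame["abs_along"].mean().reindex(frames) * scale

    base = _SIGMA_PX * scale * np.sqrt(1.0 + 1.0 / m)
    # scale uncertainty from the two outermost marker centroids
    rel_scale_err = math.sqrt(2.0) * _SIGMA_PX / axes["span"]
    err = np.sqrt(base**2 + (rel_scale_err * offset_cm) ** 2
                  + (disagreement / 2.0) ** 2)

    t = frames / tracks.frame_rate
    v = vert.to_numpy()
    h = horiz.to_numpy()
    return DisplacementSeries(
        time=np.asarray(t, dtype=float),
        vertical_cm=v - v[0],
        horizontal_cm=h - h[0],
        err_cm=err.to_numpy(),
    )


def vertical_speed(disp: DisplacementSeries) -> tuple[float, float]:
    """Mean vertical speed (cm/s) and its propagated error.

    The speed is the mean of frame-to-frame finite differences (equal to
    net displacement over elapsed time for a complete record). The error
    treats each frame's position error as independent when combining the
    differences, which is conservative since adjacent differences share a
    sample.
    """
    if len(disp.time) < 2:
        raise ValueError("need at least two samples for a speed")
    dt = np.diff(disp.time)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    rates = np.diff(disp.vertical_cm) / dt
    mean = float(np.mean(rates))
    var_sum = np.sum((disp.err_cm[:-1] ** 2 + disp.err_cm[1:] ** 2) / dt**2)
    err = float(np.sqrt(var_sum)) / len(rates)
    return mean, err


def decompose_horizontal(
    disp: DisplacementSeries,
) -> tuple[np.ndarray, float, float]:
    """Detrend the horizontal component; estimate oscillation amplitude and
    period (surface-current signature).

    amplitude = half peak-to-trough of the linearly detrended series;
    period from the dominant positive-lag autocorrelation peak (NaN, with a
    warning, when the record is too short to contain one). A plain
    least-squares line absorbs part of any sinusoid (t correlates with sin
    over a finite window), so once a period is found the line is re-fitted
    jointly with a sinusoid at that period and only the line is removed.
    """
    t = disp.time
    h = disp.horizontal_cm
    if len(t) < 3:
        raise ValueError("record too short to decompose")
    coef = np.polyfit(t, h, 1)
    detrended = h - np.polyval(coef, t)

    def _period_of(series: np.ndarray) -> float:
        n = len(series)
        centered = series - series.mean()
        denom = float(np.dot(centered, centered))
        if denom <= 0:
            return float("nan")
        ac = np.correlate(centered, centered, mode="full")[n - 1:] / denom
        # autocorrelation is only trustworthy to about half the record
        ac = ac[: n // 2 + 1]
        peaks, props = find_peaks(ac, height=0.1)
        if len(peaks) == 0:
            return float("nan")
        best = peaks[np.argmax(props["peak_heights"])]
        return float(best * np.mean(np.diff(t)))

    period = _period_of(detrended)
    if math.isfinite(period):
        # joint line + sinusoid fit; remove only the refined line
        omega = 2 * np.pi / period
        design = np.column_stack(
            [np.ones_like(t), t, np.sin(omega * t), np.cos(omega * t)]
        )
        beta, *_ = np.linalg.lstsq(design, h, rcond=None)
        detrended = h - (beta[0] + beta[1] * t)
        period = _period_of(detrended)
    else:
        warnings.warn(
            "record shorter than one oscillation; period not estimated",
            stacklevel=2,
        )
    amplitude = float((detrended.max() - detrended.min()) / 2.0)
    return detrended, amplitude, period


def measured_frequency(event_times, window: float) -> float:
    """Pulse rate (Hz) as the event count within [0, window) over window."""
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(event_times, dtype=float)
    return float(np.count_nonzero((times >= 0) & (times < window)) / window)
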