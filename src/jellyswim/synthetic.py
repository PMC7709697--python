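"""Ground-truthed synthetic inputs mirroring the field-acquisition setup.

gen_track emulates a diver-held camera filming a biohybrid jellyfish
ascending past a vertical rope with markers every 30.5 cm: steady vertical
ascent, sinusoidal horizontal drift from surface currents, smooth camera
motion shared by housing and markers, Gaussian centroid noise, and
integer-pixel quantization. gen_pulse_times emulates the superposition of
controller-driven and endogenous pulse trains. gen_morphology sweeps bell
shapes and pulse timings around the measured envelope of the two field
animals.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Morphology
from .kinematics import PulseProgram
from .tracking import TrackSeries

__all__ = [
    "SyntheticTrackSpec",
    "SyntheticPulseSpec",
    "TrackGroundTruth",
    "gen_track",
    "gen_pulse_times",
    "gen_morphology",
]


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Scene and acquisition parameters for one synthetic dive video.

    Defaults reproduce the field conditions: 30 fps 1920x1080 video, rope
    markers every 30.5 cm, few-cm/s ascent with a few-cm horizontal sway,
    and roughly one-pixel centroid noise on top of integer quantization.
    """

    true_speed: float = 5.0          # cm/s ascent
    duration: float = 20.0           # s
    frame_rate: float = 30.0         # Hz
    cm_per_px: float = 0.3           # world scale of the camera view
    horiz_amp: float = 3.0           # cm, surface-current sway amplitude
    horiz_period: float = 5.0        # s, sway period
    pixel_noise_sd: float = 1.0      # px, Gaussian centroid noise
    marker_spacing: float = 30.5     # cm
    n_markers: int | None = None     # auto: enough to cover the ascent
    camera_drift_amp_px: float = 40.0
    camera_drift_period_s: float = 7.0
    start_height: float = 15.0       # cm above the lowest marker
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "frame_rate", "cm_per_px", "marker_spacing",
                     "horiz_period", "camera_drift_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("true_speed", "horiz_amp", "pixel_noise_sd",
                     "camera_drift_amp_px", "start_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SyntheticPulseSpec:
    """Superposed controller and endogenous pulse trains.

    Controller events are strictly periodic; endogenous events are periodic
    with optional Gaussian jitter and a phase offset (drawn from the seed
    when not given). Events closer than the refractory gap merge into one,
    the simplest mechanism that makes measured counts summative with
    saturation.
    """

    controller_freq: float = 0.50    # Hz; 0, 0.50, 0.75, 1.00 were tested
    endogenous_freq: float = 0.10    # Hz; 0.09-0.50 observed unstimulated
    jitter_sd: float = 0.0           # s
    duration: float = 20.0           # s
    endogenous_phase: float | None = None
    refractory: float = 0.25         # s, merge window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.controller_freq < 0 or self.endogenous_freq < 0:
            raise ValueError("frequencies must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.jitter_sd < 0 or self.refractory < 0:
            raise ValueError("jitter_sd and refractory must be non-negative")


@dataclass(frozen=True)
class TrackGroundTruth:
    """What the generator actually drew, for recovery checks."""

    speed: float
    horiz_amp: float
    horiz_period: float
    cm_per_px: float
    start_height: float


def gen_track(spec: SyntheticTrackSpec) -> tuple[TrackSeries, TrackGroundTruth]:
    """Render one synthetic centroid track series plus its ground truth.

    The camera follows the animal vertically (markers sweep through the
    frame) with an added sinusoidal pixel drift applied identically to all
    centroids, so marker-relative positions are unaffected by camera
    motion. Raises if the scene leaves any frame without a visible marker.
    """
    rng = np.random.default_rng(spec.seed)
    W, H = 1920, 1080
    n_frames = int(round(spec.duration * spec.frame_rate)) + 1
    frames = np.arange(n_frames)
    t = frames / spec.frame_rate

    # world trajectory (cm); rope at world x = 0, marker k at height k*spacing
    y_h = spec.start_height + spec.true_speed * t
    x_h = spec.horiz_amp * np.sin(2 * np.pi * t / spec.horiz_period)

    n_markers = spec.n_markers
    if n_markers is None:
        top = y_h[-1] + H / 2 * spec.cm_per_px
        n_markers = int(math.ceil(top / spec.marker_spacing)) + 1

    drift_x = spec.camera_drift_amp_px * np.sin(
        2 * np.pi * t / spec.camera_drift_period_s
    )
    drift_y = spec.camera_drift_amp_px * np.cos(
        2 * np.pi * t / spec.camera_drift_period_s + 1.0
    )

    def project(xw, yw):
        # camera centre tracks the housing vertically, rope horizontally
        xp = W / 2 + (xw - 0.0) / spec.cm_per_px + drift_x
        yp = H / 2 - (yw - y_h) / spec.cm_per_px + drift_y
        return xp, yp

    def noisy(xp, yp):
        if spec.pixel_noise_sd > 0:
            xp = xp + rng.normal(0, spec.pixel_noise_sd, size=np.shape(xp))
            yp = yp + rng.normal(0, spec.pixel_noise_sd, size=np.shape(yp))
        if spec.quantize:
            xp, yp = np.round(xp), np.round(yp)
        return xp, yp

    rows = []
    hx, hy = noisy(*project(x_h, y_h))
    if np.any((hx < 0) | (hx > W) | (hy < 0) | (hy > H)):
        raise ValueError("housing leaves the camera frame; adjust the spec")
    for fr in frames:
        rows.append((int(fr), t[fr], "housing", hx[fr], hy[fr]))

    for k in range(n_markers):
        color = "red" if k % 2 == 0 else "yellow"
        label = f"marker_{color}_{k}"
        mx, my = noisy(*project(np.zeros(n_frames), np.full(n_frames, k * spec.marker_spacing)))
        visible = (mx >= 0) & (mx <= W) & (my >= 0) & (my <= H)
        for fr in frames[visible]:
            rows.append((int(fr), t[fr], label, mx[fr], my[fr]))

    data = pd.DataFrame(rows, columns=["frame", "time_s", "label", "x_px", "y_px"])
    n_mk = data[data["label"] != "housing"].groupby("frame").size()
    if len(n_mk) < n_frames or (n_mk < 1).any():
        raise ValueError("a frame has no visible marker; adjust the spec")

    tracks = TrackSeries(data=data, frame_rate=spec.frame_rate,
                         frame_width=W, frame_height=H)
    truth = TrackGroundTruth(
        speed=spec.true_speed,
        horiz_amp=spec.horiz_amp,
        horiz_period=spec.horiz_period,
        cm_per_px=spec.cm_per_px,
        start_height=spec.start_height,
    )
    return tracks, truth


def gen_pulse_times(spec: SyntheticPulseSpec) -> np.ndarray:
    """Merged controller + endogenous pulse event times within [0, duration)."""
    rng = np.random.default_rng(spec.seed)
    events = []
    if spec.controller_freq > 0:
        events.append(np.arange(0.0, spec.duration, 1.0 / spec.controller_freq))
    if spec.endogenous_freq > 0:
        period = 1.0 / spec.endogenous_freq
        phase = spec.endogenous_phase
        if phase is None:
            phase = float(rng.uniform(0, period))
        endo = np.arange(phase, spec.duration, period)
        if spec.jitter_sd > 0:
            endo = endo + rng.normal(0, spec.jitter_sd, size=endo.shape)
        events.append(endo)
    if not events:
        return np.empty(0)
    merged = np.sort(np.concatenate(events))
    merged = merged[(merged >= 0) & (merged < spec.duration)]
    kept = []
    for e in merged:
        if not kept or e - kept[-1] >= spec.refractory:
            kept.append(e)
    return np.asarray(kept)


# measured envelope of the two field animals
_ENVELOPE = {
    "d_r": (9.8, 11.3),
    "delta_d": (5.0, 6.0),
    "h_r": (4.2, 4.4),
    "delta_h": (1.0, 1.0),
    "h_j": (2.0, 2.0),
    "t_c": (0.70, 0.87),
    "t_r": (0.73, 0.90),
    "f": (0.09, 0.81),
}


def gen_morphology(n: int, seed: int = 0) -> list[tuple[Morphology, PulseProgram]]:
    """Sample n (Morphology, PulseProgram) pairs for property sweeps.

    Uniform draws within +-25% of the measured envelope of the two field
    animals; the shape invariants (delta_d < d_r, h_j < h_r) are enforced
    by construction, and frequency is capped at the 1.4 Hz physiological
    ceiling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(key):
        lo, hi = _ENVELOPE[key]
        return rng.uniform(0.75 * lo, 1.25 * hi, size=n)

    d_r = draw("d_r")
    delta_d = np.minimum(draw("delta_d"), 0.9 * d_r)
    h_r = draw("h_r")
    delta_h = draw("delta_h")
    h_j = np.minimum(draw("h_j"), 0.9 * h_r)
    t_c = draw("t_c")
    t_r = draw("t_r")
    f = np.minimum(draw("f"), 1.4)

    out = []
    for i in range(n):
        out.append(
            (
                Morphology(d_r=d_r[i], delta_d=delta_d[i], h_r=h_r[i],
                           delta_h=delta_h[i], h_j=h_j[i]),
                PulseProgram(f=f[i], t_c=t_c[i], t_r=t_r[i]),
            )
        )
    return out
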