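"""Prescribed periodic bell kinematics d(t), h(t) and their rates.

A pulse cycle of period 1/f consists of a contraction of duration t_c
(diameter shrinks by up to delta_d while height grows by up to delta_h),
a relaxation of duration t_r back toward the relaxed shape, and — when
1/f >= t_c + t_r — a coast phase with no shape change.

When the drive period is shorter than t_c + t_r the relaxation is cut off
by the next contraction: the bell never fully relaxes, the excursion
amplitude shrinks, and the mean shape sits in a more contracted state.
Contraction always ramps over its full t_c toward the fully contracted
shape, from whatever partially relaxed shape the previous cycle left.

The shape is parameterised by a contraction fraction lam in [0, 1]
(0 = relaxed, 1 = fully contracted):

    d(t) = d_r - lam(t) * delta_d,    h(t) = h_r + lam(t) * delta_h.

Ramps are C1 cosine smoothsteps s(x) = (1 - cos(pi x))/2 by default
(zero shape rate at every completed phase boundary), or linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .geometry import Morphology

__all__ = [
    "PulseProgram",
    "BellState",
    "PhaseSchedule",
    "period_schedule",
    "bell_state",
    "volume_rate",
    "steady_start_fraction",
]

_PHASES = np.array(["contracting", "relaxing", "coasting"])


@dataclass(frozen=True)
class PulseProgram:
    """Pulse timing: drive frequency and contraction/relaxation durations.

    f is the *measured* swimming frequency (controller plus endogenous
    pulses) that drives the model.
    """

    f: float
    t_c: float
    t_r: float
    waveform: str = "cosine"

    def __post_init__(self) -> None:
        if not (self.f > 0 and math.isfinite(self.f)):
            raise ValueError("pulse frequency f must be positive")
        if self.t_c <= 0 or self.t_r <= 0:
            raise ValueError("t_c and t_r must be positive")
        if self.waveform not in ("cosine", "linear"):
            raise ValueError("waveform must be 'cosine' or 'linear'")

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass(frozen=True)
class BellState:
    """Instantaneous bell shape and rates; fields may be scalars or arrays."""

    t: object
    h_t: object
    d_t: object
    dh_dt: object
    dd_dt: object
    dVsub_dt: object
    phase: object


class PhaseSchedule(NamedTuple):
    contract: float
    relax: float
    coast: float


def period_schedule(pulse: PulseProgram) -> PhaseSchedule:
    """Split one drive period into (contract, relax, coast) durations.

    The contraction keeps its full t_c while the period allows; the
    relaxation absorbs the truncation, and the coast phase exists only for
    1/f >= t_c + t_r. Durations are non-negative and sum to 1/f.
    """
    period = pulse.period
    contract = min(pulse.t_c, period)
    relax = min(pulse.t_r, period - contract)
    coast = period - contract - relax
    return PhaseSchedule(contract, relax, max(coast, 0.0))


def _ramp(x: np.ndarray, waveform: str) -> tuple[np.ndarray, np.ndarray]:
    """Ramp s(x) on [0, 1] and its derivative s'(x)."""
    if waveform == "cosine":
        return (1.0 - np.cos(np.pi * x)) / 2.0, np.pi * np.sin(np.pi * x) / 2.0
    return x, np.ones_like(x)


def _ramp_scalar(x: float, waveform: str) -> float:
    if waveform == "cosine":
        return (1.0 - math.cos(math.pi * x)) / 2.0
    return x


def steady_start_fraction(pulse: PulseProgram) -> float:
    """Contraction fraction at the start of a steady-state cycle.

    Zero in the untruncated regime (full relaxation); positive once
    1/f < t_c + t_r because the relaxation is interrupted.
    """
    sched = period_schedule(pulse)
    if sched.contract < pulse.t_c:
        # Contraction itself truncated: lam_{n+1} = lam_n + (1-lam_n) s;
        # fixed point is full contraction.
        return 1.0
    s_relax = _ramp_scalar(sched.relax / pulse.t_r, pulse.waveform)
    return 1.0 - s_relax


def _cycle_start_fractions(n_cycles: int, pulse: PulseProgram) -> np.ndarray:
    """lam at the onset of cycles 0..n_cycles-1, starting fully relaxed."""
    sched = period_schedule(pulse)
    starts = np.empty(max(n_cycles, 1))
    starts[0] = 0.0
    if n_cycles <= 1:
        return starts
    if sched.contract >= pulse.t_c:
        # Contraction completes every cycle, so every later cycle starts at
        # the same partially (or fully) relaxed fraction.
        starts[1:] = steady_start_fraction(pulse)
        return starts
    s_c = _ramp_scalar(sched.contract / pulse.t_c, pulse.waveform)
    lam = 0.0
    for k in range(1, n_cycles):
        lam = lam + (1.0 - lam) * s_c
        starts[k] = lam
    return starts


def _shape_fraction(
    t: np.ndarray, pulse: PulseProgram
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contraction fraction lam(t), rate dlam/dt, and phase code (0/1/2)."""
    sched = period_schedule(pulse)
    period = pulse.period
    cycle = np.floor(t * pulse.f).astype(int)
    tau = t - cycle * period

    starts = _cycle_start_fractions(int(cycle.max()) + 1, pulse)
    lam0 = starts[cycle]

    lam = np.empty_like(tau)
    rate = np.zeros_like(tau)
    phase = np.full(tau.shape, 2, dtype=int)

    contracting = tau < sched.contract
    relaxing = (~contracting) & (tau < sched.contract + sched.relax)

    # contraction: lam0 -> 1 over full t_c (possibly cut by period end)
    xc = tau[contracting] / pulse.t_c
    s, ds = _ramp(xc, pulse.waveform)
    lam[contracting] = lam0[contracting] + (1.0 - lam0[contracting]) * s
    rate[contracting] = (1.0 - lam0[contracting]) * ds / pulse.t_c
    phase[contracting] = 0

    # shape reached at end of contraction phase
    s_end = _ramp_scalar(min(sched.contract / pulse.t_c, 1.0), pulse.waveform)
    lam_c = lam0 + (1.0 - lam0) * s_end

    # relaxation: lam_c -> 0 over full t_r (cut by period end when truncated)
    xr = (tau[relaxing] - sched.contract) / pulse.t_r
    s, ds = _ramp(xr, pulse.waveform)
    lam[relaxing] = lam_c[relaxing] * (1.0 - s)
    rate[relaxing] = -lam_c[relaxing] * ds / pulse.t_r
    phase[relaxing] = 1

    # coast: frozen at the end-of-relaxation shape
    coasting = ~(contracting | relaxing)
    if np.any(coasting):
        s_relax = _ramp_scalar(sched.relax / pulse.t_r, pulse.waveform)
        lam[coasting] = lam_c[coasting] * (1.0 - s_relax)

    return lam, rate, phase


def bell_state(t, morph: Morphology, pulse: PulseProgram) -> BellState:
    """Evaluate the prescribed bell waveform at time(s) t >= 0.

    Returns a BellState with instantaneous height, diameter, their analytic
    rates, the subumbrellar volume rate, and a phase tag. Accepts a scalar
    or an array of times.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    lam, dlam, phase_code = _shape_fraction(t_arr, pulse)

    d_t = morph.d_r - lam * morph.delta_d
    h_t = morph.h_r + lam * morph.delta_h
    dd_dt = -morph.delta_d * dlam
    dh_dt = morph.delta_h * dlam

    # chain rule on V_sub = (pi/6) d^2 (h - h_j); h > h_j guaranteed since
    # h >= h_r > h_j
    cavity = h_t - morph.h_j
    dV = (np.pi / 3.0) * d_t * cavity * dd_dt + (np.pi / 6.0) * d_t**2 * dh_dt

    phase = _PHASES[phase_code]
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return BellState(
            t=float(t_arr[0]),
            h_t=float(h_t[0]),
            d_t=float(d_t[0]),
            dh_dt=float(dh_dt[0]),
            dd_dt=float(dd_dt[0]),
            dVsub_dt=float(dV[0]),
            phase=str(phase[0]),
        )
    return BellState(t=t_arr, h_t=h_t, d_t=d_t, dh_dt=dh_dt, dd_dt=dd_dt,
                     dVsub_dt=dV, phase=phase)


def volume_rate(state: BellState, morph: Morphology):
    """Subumbrellar volume rate dV_sub/dt (cm^3 s^-1) from a bell state.

    Chain rule on the hemiellipsoidal cavity volume; negative while the
    cavity shrinks (jet expulsion), positive during refill.
    """
    d_t = np.asarray(state.d_t, dtype=float)
    h_t = np.asarray(state.h_t, dtype=float)
    cavity = np.maximum(h_t - morph.h_j, 0.0)
    out = (
        (np.pi / 3.0) * d_t * cavity * np.asarray(state.dd_dt)
        + (np.pi / 6.0) * d_t**2 * np.asarray(state.dh_dt)
    )
    return out if out.ndim else float(out)
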