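"""Bell waveform: phase schedule, continuity, analytic rates, truncation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jellyswim import PulseProgram, bell_state, period_schedule, volume_rate
from jellyswim.geometry import Morphology, subumbrellar_volume
from jellyswim.kinematics import steady_start_fraction


@pytest.fixture(scope="module")
def morph1(request):
    return Morphology(d_r=11.3, delta_d=6.0, h_r=4.4, delta_h=1.0, h_j=2.0)


@pytest.mark.parametrize(
    "f, t_c, t_r, expected",
    [
        (0.50, 0.70, 0.73, (0.70, 0.73, 0.57)),          # coast present
        (1.0 / 1.43, 0.70, 0.73, (0.70, 0.73, 0.0)),     # boundary: coast 0
        (0.81, 0.70, 0.73, (0.70, 1.0 / 0.81 - 0.70, 0.0)),  # truncated relax
        (2.0, 0.70, 0.73, (0.50, 0.0, 0.0)),             # truncated contraction
    ],
)
def test_period_schedule_partitions_the_period(f, t_c, t_r, expected):
    sched = period_schedule(PulseProgram(f=f, t_c=t_c, t_r=t_r))
    assert sched == pytest.approx(expected, abs=1e-12)
    assert sum(sched) == pytest.approx(1.0 / f)
    assert all(s >= 0 for s in sched)


def test_invalid_pulse_rejected():
    with pytest.raises(ValueError):
        PulseProgram(f=0.0, t_c=0.7, t_r=0.73)
    with pytest.raises(ValueError):
        PulseProgram(f=0.5, t_c=-0.1, t_r=0.73)


def test_rest_state_at_cycle_start(morph1):
    st0 = bell_state(0.0, morph1, PulseProgram(f=0.5, t_c=0.7, t_r=0.73))
    assert st0.d_t == pytest.approx(morph1.d_r)
    assert st0.h_t == pytest.approx(morph1.h_r)
    assert st0.dd_dt == pytest.approx(0.0, abs=1e-12)
    assert st0.dh_dt == pytest.approx(0.0, abs=1e-12)


def test_full_contraction_reached_at_t_c(morph1):
    pulse = PulseProgram(f=0.5, t_c=0.7, t_r=0.73)
    st_c = bell_state(0.7, morph1, pulse)
    assert st_c.d_t == pytest.approx(morph1.d_r - morph1.delta_d)
    assert st_c.h_t == pytest.approx(morph1.h_r + morph1.delta_h)


def test_cosine_ramp_has_zero_rate_at_endpoints(morph1):
    pulse = PulseProgram(f=0.5, t_c=0.7, t_r=0.73)
    eps = 1e-9
    st_c = bell_state(0.7 - eps, morph1, pulse)
    assert abs(st_c.dd_dt) < 1e-6
    st_coast = bell_state(1.6, morph1, pulse)  # inside the coast phase
    assert st_coast.phase == "coasting"
    assert st_coast.dd_dt == 0.0 and st_coast.dh_dt == 0.0
    assert st_coast.dVsub_dt == 0.0


@pytest.mark.parametrize("waveform", ["cosine", "linear"])
@given(
    f=st.floats(0.09, 1.4),
    t_c=st.floats(0.3, 1.2),
    t_r=st.floats(0.3, 1.2),
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_shape_continuous_at_phase_boundaries(waveform, f, t_c, t_r):
    """d(t), h(t) are continuous across every phase boundary, including the
    cycle wrap in the truncated regime."""
    morph = Morphology(d_r=11.3, delta_d=6.0, h_r=4.4, delta_h=1.0, h_j=2.0)
    pulse = PulseProgram(f=f, t_c=t_c, t_r=t_r, waveform=waveform)
    sched = period_schedule(pulse)
    period = 1.0 / f
    eps = 1e-9
    boundaries = []
    for k in (1, 2, 3):  # skip the startup cycle, test steady cycles
        base = k * period
        boundaries += [base, base + sched.contract,
                       base + sched.contract + sched.relax]
    for b in boundaries:
        before = bell_state(b - eps, morph, pulse)
        after = bell_state(b + eps, morph, pulse)
        assert after.d_t == pytest.approx(before.d_t, abs=1e-6)
        assert after.h_t == pytest.approx(before.h_t, abs=1e-6)


@pytest.mark.parametrize("waveform", ["cosine", "linear"])
@pytest.mark.parametrize("f", [0.20, 0.53, 0.81, 1.00])
def test_analytic_rates_match_finite_differences(morph1, waveform, f):
    pulse = PulseProgram(f=f, t_c=0.7, t_r=0.73, waveform=waveform)
    sched = period_schedule(pulse)
    period = 1.0 / f
    t = np.linspace(0.01, 4 * period, 700)
    dt = 1e-5
    # keep clear of phase boundaries where one-sided kinks break central FD
    tau = t % period
    cuts = np.array([0.0, sched.contract, sched.contract + sched.relax, period])
    dist = np.min(np.abs(tau[:, None] - cuts[None, :]), axis=1)
    t = t[dist > 10 * dt]

    s0 = bell_state(t, morph1, pulse)
    sp = bell_state(t + dt, morph1, pulse)
    sm = bell_state(t - dt, morph1, pulse)
    for analytic, plus, minus in (
        (s0.dd_dt, sp.d_t, sm.d_t),
        (s0.dh_dt, sp.h_t, sm.h_t),
    ):
        fd = (plus - minus) / (2 * dt)
        scale = np.max(np.abs(analytic)) + 1e-12
        assert np.max(np.abs(fd - analytic)) / scale < 1e-6


def test_untruncated_cycle_is_shape_periodic(morph1):
    pulse = PulseProgram(f=0.5, t_c=0.7, t_r=0.73)
    t = np.array([0.0, 0.3, 1.1])
    a = bell_state(t + 2.0, morph1, pulse)  # one full period later
    b = bell_state(t + 4.0, morph1, pulse)
    np.testing.assert_allclose(a.d_t, b.d_t, atol=1e-12)
    np.testing.assert_allclose(a.h_t, b.h_t, atol=1e-12)
    # net V_sub change over an untruncated period is zero
    v0 = subumbrellar_volume(a.h_t[0], a.d_t[0], morph1.h_j)
    v1 = subumbrellar_volume(b.h_t[0], b.d_t[0], morph1.h_j)
    assert v1 == pytest.approx(v0, abs=1e-10)


def test_truncated_cycle_never_fully_relaxes(morph1):
    """At 1.00 Hz the period is shorter than t_c + t_r: the muscle cannot
    finish relaxing, so max diameter over a steady cycle stays below d_r and
    the mean shape is more contracted than in the untruncated regime."""
    pulse = PulseProgram(f=1.0, t_c=0.7, t_r=0.73)
    t = np.linspace(2.0, 3.0, 2001)  # steady cycle (past the first cycle)
    st_tr = bell_state(t, morph1, pulse)
    assert np.max(st_tr.d_t) < morph1.d_r
    assert steady_start_fraction(pulse) > 0

    slow = PulseProgram(f=0.5, t_c=0.7, t_r=0.73)
    t_slow = np.linspace(2.0, 4.0, 4001)
    st_slow = bell_state(t_slow, morph1, slow)
    assert np.mean(st_tr.d_t) < np.mean(st_slow.d_t)
    assert steady_start_fraction(slow) == pytest.approx(0.0, abs=1e-12)


def test_volume_rate_matches_bell_state_and_signs(morph1):
    pulse = PulseProgram(f=0.5, t_c=0.7, t_r=0.73)
    st_mid = bell_state(0.35, morph1, pulse)  # mid-contraction
    assert st_mid.phase == "contracting"
    assert volume_rate(st_mid, morph1) == pytest.approx(st_mid.dVsub_dt)
    assert st_mid.dVsub_dt < 0  # cavity shrinking while jetting
    # finite-difference cross-check of the volume rate itself
    dt = 1e-6
    vp = subumbrellar_volume(
        bell_state(0.35 + dt, morph1, pulse).h_t,
        bell_state(0.35 + dt, morph1, pulse).d_t,
        morph1.h_j,
    )
    vm = subumbrellar_volume(
        bell_state(0.35 - dt, morph1, pulse).h_t,
        bell_state(0.35 - dt, morph1, pulse).d_t,
        morph1.h_j,
    )
    assert (vp - vm) / (2 * dt) == pytest.approx(st_mid.dVsub_dt, rel=1e-6)
    # contraction ends with a smaller cavity than it started
    s0, s1 = bell_state(0.0, morph1, pulse), bell_state(0.7, morph1, pulse)
    assert subumbrellar_volume(s1.h_t, s1.d_t, morph1.h_j) < subumbrellar_volume(
        s0.h_t, s0.d_t, morph1.h_j
    )
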