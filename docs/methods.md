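# Methods

## Model

A pulsing medusa is treated as an axisymmetric jet propulsor with
prescribed shape kinematics. The state is the instantaneous bell height
`h_t` and diameter `d_t`; the bell body is an oblate hemiellipsoid of
revolution (semi-axes `d_t/2, d_t/2, h_t`), so

- body volume `V_j = (2/3)π (d_t/2)² h_t`,
- projected area `A_j = π (d_t/2)²`,
- subumbrellar cavity volume `V_sub = (2/3)π (d_t/2)² (h_t − h_j)`, the
  manubrium tissue height `h_j` reducing the cavity depth,
- orifice area `A_sub = π (d_t/2)²` at the instantaneous diameter.

The hemiellipsoid closed forms are a modelling choice: the source
measurements provide only the six scalars (`d_r, Δd, h_r, Δh, h_j` and the
timings), and a hemiellipsoid is the standard idealisation for oblate
medusae. `A_sub` is read as the circular bell opening because the thrust
law below is a jet momentum flux through the orifice; a curved-surface
reading would only rescale thrust by a shape-dependent constant.

Vertical velocity `u(t)` obeys

    (m_j + α ρ_j V_j) du/dt = T − D − m_j g_net

- `T = ρ_w (dV_sub/dt)² / A_sub`, applied forward while the cavity
  contracts (`dV_sub/dt < 0`). The momentum-flux form is used because it is
  the only dimensionally consistent reading of a jet thrust built from
  `ρ_w`, `A_sub` and `dV_sub/dt`; the product form `ρ_w A_sub (dV/dt)²`
  has units of dyn·cm⁴ and cannot enter a force balance.
- `D = ½ C_d ρ_w A_j u|u|` — written with `u|u|` rather than `u²` so drag
  opposes motion in either direction. `C_d = 0.42` is held constant (the
  operating Reynolds number ≈ 325 varies too little over a pulse to justify
  a Re-dependent law).
- acceleration reaction with `α = (2 h_t/d_t)^1.4`, kept on the inertial
  side as an effective added mass `α ρ_j V_j` evaluated at the
  instantaneous shape. The body's inertial mass `m_j = ρ_j V_j(h_r, d_r)`
  is constant (mass is conserved even as the idealised volume pulsates).
- `g_net` (net weight minus buoyancy) defaults to 0: the field system is
  ballasted neutrally buoyant and the tissue density `ρ_j` defaults to
  seawater's 1.024 g/cm³. Both are configurable.

### Refill thrust

Whether bell refill applies a rearward jet term is a genuine modelling
fork. With the measured timings the contraction (0.70–0.87 s) and
relaxation (0.73–0.90 s) last almost equally long, so a symmetric rearward
refill term cancels ~96% of the forward impulse and predicts 0.2–0.4 cm/s
— an order of magnitude below observed swimming — and negative mean speeds
in the truncated regime. Physically the intake is a broad sink flow, not a
directed jet, so its momentum flux through the orifice overstates the
rearward force badly. The default is therefore an expulsion-only jet
(`refill_thrust=False`); the flag exists and
`analysis/03_model_sensitivity.py` quantifies the alternative.

## Bell kinematics

Shape is parameterised by a contraction fraction `λ ∈ [0, 1]`
(`d = d_r − λΔd`, `h = h_r + λΔh`; contraction narrows and heightens the
bell). One drive period `1/f` is split into contraction (duration `t_c`),
relaxation (`t_r`), and a coast phase holding the relaxed shape whenever
`1/f ≥ t_c + t_r`. Ramps are cosine smoothsteps `s(x) = (1 − cos πx)/2` by
default — C¹ at completed phase boundaries, so the force law sees no rate
jumps — with a linear option.

When `1/f < t_c + t_r` the relaxation is truncated: contraction always
runs its full `t_c` toward the fully contracted shape, relaxation proceeds
toward full relaxation but stops where the period ends, and the next
contraction starts from that partially relaxed shape. Because the
contraction endpoint is shape-independent, every cycle after the first is
identical; the bell oscillates over a reduced excursion about a more
contracted mean, which is what shrinks the jet volume and the speed at
high drive frequency. The rule that contraction ramps toward the *fully*
contracted shape regardless of its starting point (rather than by a fixed
increment Δd) is the simplest reading consistent with a muscle ring that
fully activates each pulse.

Waveform sensitivity: under the default cosine ramps the short-pulse
animal's speed rises strictly across its measured band 0.09–0.81 Hz; under
linear ramps the 0.81 Hz case (truncated) falls slightly below 0.53 Hz.
The qualitative slow-pulse result (0.75 Hz slower than 0.53 Hz) holds
under both shapes. Reported results use the cosine default.

## Integration

The drive is prescribed, so thrust and effective inertia are pure
functions of time and only drag couples to `u`. The integrator is an
explicit midpoint (RK2) scheme with 100 fixed substeps per output step at
30 output steps/s, chosen to mirror the 30 fps video analysis; runs cover
10 pulse cycles from rest and the headline speed is the mean of all output
samples (transient included), with a final-cycle "steady" mean exposed as
a diagnostic. Fixed stepping keeps trajectories bit-identical across runs.
Verification: halving the substep changes a one-period mean speed by
< 1e−5 relative; an independent adaptive DOP853 integration of the same
right-hand side agrees to < 0.001% mean speed on all nine measured cases
(tested, and recomputed by `scripts/acceptance.py`). Non-finite velocities
abort with an error naming the failure time.

## Tracking pipeline

Input is a labeled centroid table (frame, time, label, pixel x/y) at
30 fps — segmentation of raw video is out of scope. Rope markers carry
their index in the label (`marker_red_0`, `marker_yellow_1`, …, red even,
yellow odd, 30.5 cm apart), so marker `k` sits at a known height
`k × 30.5 cm` on the rope.

- **Calibration**: per frame, `cm_per_px = 30.5 × (index gap between the
  outermost visible markers) / (their pixel distance)`. Frames with fewer
  than two markers inherit the nearest calibrated frame's scale and are
  flagged.
- **Stitching**: per frame the housing position is anchored to every
  visible marker — rope height of the marker plus the housing's pixel
  offset projected on the rope axis, scaled. Camera motion cancels because
  housing and markers share it. Red-anchored and yellow-anchored estimates
  are averaged where both exist and their disagreement is folded into the
  error; the series is zeroed at the first frame, ascent positive.
- **Error model**: centroids are assumed accurate to ~1 px; an sd of
  `sqrt(1² + 1/12)` px (accuracy plus integer-quantization variance) is
  propagated through the scale into each frame's `err_cm`, together with
  the scale's own uncertainty (two outermost centroids) times the
  housing–marker offset, and the red/yellow disagreement.
- **Speed**: mean of frame-to-frame differences (equal to net displacement
  over elapsed time for complete records). Its error combines the
  per-frame errors as if independent; since adjacent differences share a
  frame, this is deliberately conservative — the telescoped endpoint-only
  error would be ~√N smaller — and it matches the few-tenths-cm/s error
  bars typical of this kind of video analysis.
- **Drift decomposition**: the horizontal component is linearly detrended;
  a plain least-squares line absorbs part of any sinusoid, so once the
  oscillation period is found (dominant autocorrelation peak, accepted
  only at lags up to half the record) the line is re-fitted jointly with a
  sinusoid at that period and only the line removed. Amplitude is half the
  peak-to-trough of the detrended series — a max statistic, biased upward
  by pixel noise (~+0.5 cm at one-pixel noise and 0.3 cm/px); the period
  estimate is unbiased. Records shorter than one oscillation warn and
  return amplitude only.
- **Pulse frequency**: event count in `[0, window)` over the window.

## Synthetic data

`gen_track` renders the acquisition geometry the pipeline assumes: a
1920×1080, 30 fps camera that follows the animal vertically with an added
smooth sinusoidal pixel drift, a vertical rope of indexed markers, steady
ascent plus sinusoidal horizontal sway, Gaussian centroid noise (default
1 px) and integer-pixel quantization. Defaults (5 cm/s ascent, 3 cm sway
over 5 s, 20 s records) sit in the middle of the observed field regime of
2–7 cm/s ascents under 4 m/s winds. It does *not* emulate marker
occlusion, tracking dropouts, lens distortion, animal-shape segmentation
error, or non-sinusoidal currents — so passing recovery tests validates
the geometry, calibration and error propagation, not robustness to
real-video artefacts.

`gen_pulse_times` superposes a strictly periodic controller train with a
jittered periodic endogenous train (0.09–0.50 Hz is the observed
unstimulated band) and merges events closer than a 0.25 s refractory gap —
the simplest mechanism that makes measured counts summative with
saturation; it makes no claim about the real stimulated–endogenous
interaction, which is unresolved. `gen_morphology` sweeps shapes and
timings uniformly within ±25% of the two animals' measured envelope with
invariants enforced by construction, for property tests.

All generators are pure functions of their spec and seed.

## Numerical and degenerate-input conventions

- Geometry rejects non-positive lengths; the cavity height clamps at zero
  (`V_sub = 0` once `h_t ≤ h_j`, impossible under valid waveforms since
  `h ≥ h_r > h_j`).
- `period_schedule` truncates relaxation first, then contraction
  (`1/f ≤ t_c` leaves relax = 0); durations always sum to `1/f`.
- Speed–frequency tables refuse frequencies outside (0, 1.4] Hz, the
  physiological ceiling for scyphozoan muscle.
- Baselines average an animal's control (0 Hz) trials — two per animal in
  the field protocol; mixing animals raises. Theory–experiment comparison
  uses the sample SD (n−1) of absolute differences, reporting 0 for a
  single pair, and lists unmatched records instead of dropping them.
- Comparison matching treats frequencies within 1e−6 Hz as equal.

## Known limitations

- The jetting model omits rowing propulsion, passive energy recapture and
  stopping-vortex thrust, fluid–structure interaction, and any horizontal
  dynamics; it is a first-order predictor of vertical speed only.
- Model speeds depend on the ramp-shape choice at the tens-of-percent
  level (see the sensitivity table); only trends are robust.
- The absolute field numbers (maximum 6.6 cm/s, enhancements 2.3×/2.1×)
  require the per-trial field speed table, which is not available here;
  the package reproduces the model-side quantities and validates the
  measurement pipeline on synthetic ground truth instead.
- The tracking error model assumes independent per-centroid noise; real
  video has correlated failure modes (motion blur, partial occlusion) that
  the reported errors do not cover.
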