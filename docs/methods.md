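# Methods

This note documents the models, estimators, numerical choices and known
limitations behind the `heelstrike` package.

## The quantity being estimated

During the first ~30–50 ms after heel contact in walking, the heel pad,
foot and ankle compress and absorb mechanical energy. "Heel strike" is
defined here as the interval from contact onset t₀ (vertical GRF leaves
zero) to t_e, the instant of zero vertical heel velocity — equivalently
maximal vertical foot–ankle deformation. This definition deliberately
differs from ending the interval at the impact-force peak t_p: with a
viscous heel pad, peak force and peak deformation do not coincide, and
t_p < t_e whenever damping is substantial.

## Pipeline

1. **Channel reduction.** The eight plate channels (four vertical
   sensors at (±a, ±b) around the plate centre, paired shear channels)
   reduce to net force F = (fx12+fx34, fy14+fy23, Σfz_i) and surface
   COP by moment balance about the sensor plane a depth az0 below the
   surface: x_cop = (Σ x_i fz_i + az0 F_X)/F_Z, likewise for y. The
   COP is marked invalid below 10 N of vertical force (the quotient is
   ill-conditioned as F_Z → 0); the heel-point window never reaches
   those samples. The synthetic renderer implements exactly the inverse
   map (bilinear vertical split at the sensor-plane-projected COP, even
   shear split), and the round trip is tested to 1e−9.

2. **Events.** t₀ is the last sample with F_Z ≤ 2 N before the first
   sample above 10 N ("the instant at which GRF is zero" is not
   attainable verbatim on noisy channels). t_p is the first local
   maximum of F_Z within 60 ms of t₀ with prominence ≥ 5% of the window
   maximum, falling back to the window argmax for monotone transients.
   t_e is the first upward zero crossing of the vertical heel velocity
   after t₀, located to sub-sample resolution by linear interpolation;
   absence of a crossing within 100 ms is an error.

3. **Kinematics.** Marker trajectories are low-pass filtered at 100 Hz
   with a 2nd-order Butterworth applied forward–backward (zero phase,
   effective 4th order, odd-reflection padding of three filter
   lengths). The local tibia frame has z along the two-LED axis, y the
   unit vector orthogonal to z with zero global-X component and
   positive anterior component (the plane-of-progression constraint
   fixes the line; the anterior sign is this package's choice), and
   x = y × z. The COP is linearly interpolated onto kinematic
   timestamps (avoiding rotation interpolation) and transformed into
   the local frame; the heel point r_H is the component-wise
   (marginal) median of those local COP samples over a window that
   starts when F_Z first reaches 25% of the impact-peak force and ends
   with the peak at its midpoint. A geometric (Weiszfeld) median is
   available by configuration but is not the default.

4. **Energetics.** Work components W_k = ∫ F_k dS_k are trapezoidal
   integrals on the force time base (3000 Hz) with the deformation
   interpolated up from the kinematic base (1295 Hz) — the force base
   preserves the sharp impact transient in the integrand — and exact
   interval endpoints obtained by linear interpolation. Effective
   masses use the trapezoidal impulse with the same endpoint handling.
   The energy change is ΔE = ½M(v_end² − v_start²) + M g (z_end −
   z_start), negative when the effective mass loses energy; reported
   reference values for these quantities are only consistent with this
   sign convention, and it makes ΔE directly comparable to W.

## Synthetic trials

The simulator integrates a point mass (the effective foot mass)
touching down at v₀ < 0 against a viscoelastic half-space:

    M z̈ = −M g + F_c,  F_c = max(0, k δⁿ + c δ̇ δⁿ⁻¹ · r(δ)),  δ = max(0, −z)

with n = 1 (linear spring) by default and the damper ramped in over the
first 2 mm of penetration, r(δ) = min(1, δ/2 mm). The ramp is
essential: a pure Kelvin–Voigt damper jumps to c|v₀| at first contact,
a force step that no finite sampling rate integrates cleanly (it alone
puts a rate-dependent ~0.3–2% bias into the work integral) and that
real heel pads, which stiffen progressively, do not exhibit. With the
ramp the contact force is continuous, the work-integral error stays
below 0.1% across damping ratios 0–1, and doubling the force sampling
rate changes W by ~0.02%.

Integration is fixed-step classical Runge–Kutta at 10 µs, which makes
trajectories, truth energies and lift-off bit-reproducible under a
seed. The truth ledger accumulates the contact work ∫F_c ż dt, damper
dissipation and stored elastic energy by the trapezoidal rule on the
same fine grid; the bookkeeping identity |ΔKE + ΔPE − W_contact| is
verified below 1e−6 of the touchdown kinetic energy for every tested
configuration.

Rendering: the heel point touches down at a fixed plate location; the
surface COP sits at its horizontal position (drifting only if a shear
drift is prescribed; shear forces then follow a spring–damper law on
the prescribed horizontal path and are off by default). Channels are
sampled at 3000 Hz — optionally with a constant force-clock offset
(≤1 ms synchronization error) and Gaussian channel noise — markers at
1295 Hz from a rigid segment carrying the LEDs at fixed offsets, tilted
about the lateral axis by a constant angle plus an optional slow ramp,
with Gaussian noise per coordinate (0.1 mm at study level).

**Default parameters** (one trial): M = 8.5 kg, k = 15 kN/m,
c = 250 N·s/m (damping ratio ζ ≈ 0.35), v₀ = −0.57 m/s. These were
chosen once, by forward simulation, to land the trial in the regime
reported for barefoot walking at preferred speed: t_p ≈ 23 ms,
t_e ≈ 41 ms, t_e/t_p ≈ 1.8, S_Z(t_e) ≈ −12.9 mm, ΔE_e ≈ −2.4 J. The
study generator draws, per subject, body mass U(55, 95) kg, effective
mass fraction U(0.09, 0.13), k U(12, 18) kN/m, ζ U(0.30, 0.45), v₀
U(−0.70, −0.45) m/s, tilt U(0°, 8°) with ramp U(5, 20)°/s, and jitters
v₀ per trial (SD 0.03 m/s). No attempt is made to fit k and c to any
particular population; they are plausible-magnitude choices.

## What the simulator does and does not emulate

Emulated: distinct force/kinematic rates, sub-millisecond clock offset,
marker noise at the motion-capture accuracy level, channel noise,
millimetre deformation with an impact transient, damped phase lag
between peak force and peak deformation, rigid-segment tilt.

Not emulated: multi-segment foot mechanics, rolling of the contact
point (so the COP is genuinely stationary under the heel — on real
feet it migrates anteriorly), skin-motion artifact, wobbling soft
tissue, and any elastic-vs-dissipative partition of the absorbed
energy. Passing tests therefore demonstrate correctness of the
estimators under the stated contact model and noise, not robustness to
every artifact of real gait data.

One consequence of the geometry is worth stating precisely: the plate
COP lies on the surface while the bone-fixed heel point penetrates it
by δ(t), so the local-frame COP carries +δ(t) in its z coordinate and
the median-based r_H is biased upward (toward the surface) by the
median penetration over the estimation window — in x and y the
recovery is exact to numerical precision on noiseless trials. The same
bias exists for real data; it is a property of the COP-median
definition, not of the simulator. It is harmless downstream: under
pure translation the deformation S(t) is independent of r_H entirely,
and under the slow tilts of gait the leakage is second order (the
sensitivity analysis, which displaces the heel point by ~1.7 cm,
changes W by under 2% on simulated trials).

## Statistics

Trials aggregate per subject (mean, sample SD with n−1); study level
reports the mean of subject means, the mean of subject SDs
(intra-subject variability), the SD of subject means (inter-subject
variability) and the range of subject means. The five energy measures
(W, W_Z, ΔE_e, ΔE_p, ΔE_p_CS) are compared with a Friedman test on the
subject-mean matrix (mid-ranks for ties, χ² with k−1 degrees of
freedom) and pairwise exact Wilcoxon signed-rank tests: zeros dropped,
mid-ranks on |differences|, two-sided p by full enumeration of the 2ⁿ
sign assignments (via the generating-polynomial recursion) for n ≤ 20,
normal approximation with tie correction above. A Bonferroni
correction over five planned pairs sets the per-test level to 0.01.

## Degenerate inputs and numerical edge cases

- Heavily damped contacts can place the impact peak at the first
  loaded sample; the peak-centred heel-point window then degenerates,
  and it is extended forward to span at least 5 ms.
- Effective-mass denominators ≤ 0 (heel not descending, or spurious
  event order) flag the trial rather than aborting the batch.
- COP samples below the force threshold are never used; marker dropout
  gaps of ≤ 5 samples are linearly interpolated, longer gaps are
  errors.
- The t_p ≤ t_e ordering is enforced softly (a warning) because the
  undamped limit makes them equal up to one sample of detection
  jitter.

## Known limitations

- Walking speed is reported as the mean anterior LED velocity over the
  capture window; with a horizontally stationary simulated heel this
  underestimates true progression speed, and the field is informative
  only for real recordings.
- The work integral inherits a ~4% sensitivity to a ±1 ms force-clock
  offset through the deformation reference R_H(t₀) (|v₀|·Δt relative
  to |S_Z(t_e)|); this is inherent to defining t₀ on the force clock
  and is the reason tight synchronization matters for this method.
- Exact signed-rank p-values with tied |differences| follow the
  mid-rank enumeration convention; implementations differ in this
  case, and agreement with external references is exact only for
  tie-free data.
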