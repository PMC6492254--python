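# Methods

## The model

A voxel is described by the 2-pool magnetization-transfer (MT) system: a
mobile free proton pool (equilibrium magnetization `m0_f`, rates `r1_f`,
`r2_f`) exchanging longitudinal magnetization with a semi-solid macromolecular
pool (`m0_m`, `r1_m`) at first-order rates `k_f` (free→macro) and `k_m`
(macro→free).  The macromolecular transverse state decays far too quickly to
represent; RF acts on that pool purely as saturation of its longitudinal
magnetization, at a rate governed by the absorption lineshape value
`g_lineshape` = G (seconds), treated as frequency independent.  The state
vector is therefore (mx_f, my_f, mz_f, mz_m).

For short-TR steady-state sequences, the time-average saturation rate over a
repetition period is

    W̄ = π (γ · B1rms)² · G,      B1rms² = (1/TR) ∫ B1²(t) dt.

With mz_m quasi-static (dmz_m/dt ≈ 0 over a TR), the free pool obeys a
single-pool longitudinal equation with effective parameters

    R1csmt(W̄) = R1f + kf · (1 − km / (R1m + km + W̄))
    M0csmt(W̄) = [R1f·M0f + km·R1m·M0m / (R1m + km + W̄)] / R1csmt(W̄)

which interpolate between the weak-saturation values (R1f + kf·R1m/(R1m+km),
≈M0f under detailed balance) and the full-saturation limits R1f + kf and
R1f·M0f/(R1f+kf).  This is the basis of controlled-saturation (CSMT)
acquisition: if every measurement deposits the same B1rms, a 2-pool tissue is
exactly a single pool with (M0csmt, T1csmt, T2 = 1/r2_f), and conventional
single-pool relaxometry is valid — with the caveat that the reported M0 and
T1 are functions of B1rms and must be quoted together with it.

Long-delay inversion recovery measures something different: the slow
eigenvalue of the coupled longitudinal system,

    R1obs = ½(R1f+kf+R1m+km) − ½√[(R1f+kf+R1m+km)² − 4(R1f·R1m + R1f·km + R1m·kf)],

which does not agree with R1csmt even at zero power (1.09 vs 1.25 s⁻¹ for the
white-matter preset).  The printed rendering of the M0csmt expression in the
source literature is ambiguous about the transient dmz_m/dt term; this
package implements the steady-state (dmz_m/dt = 0) form, which reproduces the
published full-saturation limit exactly.

## Conventions of the simulator

* RF pulses are instantaneous rotations of the free pool.  The macromolecular
  pool is multiplied per pulse by exp(−W_inst·τRF) with
  W_inst·τRF = π γ² (∫B1²dt) G — equal by construction to W̄·TR.
* The repetition period is a full TR of free evolution (exact 4-state matrix
  exponential including relaxation, exchange and precession).  The pulse
  duration τRF enters only through field amplitudes and the saturation
  exponent, never the evolution timing.  This keeps the pulsed simulator, the
  CW-equivalent model and the estimators' standard E1 = exp(−TR/T1)
  conventions mutually exact: with the macromolecular pool removed, the SPGR
  and bSSFP steady states reduce to the textbook closed forms to 1e-9.
* bSSFP phase cycling is folded into an effective precession rate
  Δω0 + Φ/TR (precession per TR = Δω0·TR + Φ); the echo is sampled at
  TE = TR/2 with the physical Δω0 only, demodulated by the exciting pulse's
  phase.  SPGR assumes ideal spoiling (transverse state zeroed each TR) and
  reports sin(α)·mz_f just before the pulse.
* Periodic steady states are fixed points of the affine one-TR map, solved by
  (I − A)x = b; if the map's condition number exceeds 1e12 the solver falls
  back to brute iteration.  Fixed points agree with ≥2000-period iteration to
  1e-9.
* A transmit-field factor scales the achieved flip linearly and the achieved
  saturation quadratically (pulsed mode), mirroring the physical residual
  B1+ sensitivity of CSMT acquisitions; T2 estimation is immune to it once
  the flip scale is supplied to the fitter.

## Accuracy of the CW approximation

The CW-equivalent model spreads the same per-TR saturation continuously.  At
the reference operating point (2.05 µT, TR 7 ms) the pulsed and CW bSSFP
steady states agree to 0.03% in magnitude; the CW-mode SPGR signal matches
the Ernst curve of (M0csmt, T1csmt) to ~1e-5 relative — the residual is the
quasi-static approximation error (mz_m ripples each TR because the pulse
perturbs mz_f), not solver error, so tests assert it at 1e-4, not at solver
precision.  The approximation degrades as the deposition becomes more
impulsive: at fixed B1rms the error grows monotonically with TR (0.03% at
7 ms → 4.4% at 100 ms).  For the same reason the full-saturation limit
T1 → 1/(R1f+kf) is a CW-limit statement: in the pulsed model at, say, 50 µT
(W̄·TR ≈ 118) mz_m is annihilated at each pulse but recovers between pulses,
and the fitted T1 saturates near 212 ms instead of 180 ms.  The B1rms sweep
driver therefore has a `model` switch; over the practical 0.2–2.0 µT range
the pulsed sweep tracks 1/R1csmt(W̄) within 2% (noiselessly, within 0.6%).

## RF pulse design

The CSMT pulse is a 3-band waveform B1(t) = (αf/αref)·B1ref(t) +
κ·B1ref(t)·cos(2πΔt): the baseband sets the free-pool flip (γ∫B1dt), the ±Δ
sidebands restore the energy (∫B1²dt) of the reference rotation αref.  κ
solves the discretized energy constraint — a quadratic whose cross term
∫B1ref²cos(2πΔt)dt is kept, so energy conservation holds to machine precision
for any Δ.  Of the two roots the smaller-magnitude one is taken: it is the
branch continuous with κ = 0 at αf = αref, and its magnitude decreases
strictly as αf grows.  Defaults: rectangular reference envelope (pluggable
Hann-sinc alternative), τRF = 0.614 ms, TR = 7 ms, Δ = 8 kHz.  Δ is
physically inconsequential here because G is frequency independent; a warning
is emitted if Δ·τRF < 2 (sidebands not spectrally separated).  Waveforms are
real envelopes sampled at midpoints of a 0.1 µs grid; flip angle, energy and
B1rms use the midpoint rule (exact for rectangular envelopes, converged to
~1e-7 for 8 kHz-modulated ones).  Both 65° and 68° reference flips appear in
the validation studies; the Monte Carlo uses 65°, the pulsed-vs-CW comparison
68°, matching each study's own configuration.

## Estimators

* DESPOT1: ordinary least squares on S/sinα vs S/tanα of SPGR magnitudes;
  slope = E1.  Slope outside (0,1) is flagged, not raised.
* DESPOT2: the same linearization on Φ=π bSSFP magnitudes, with
  E2 = (E1−m)/(1−m·E1) given the (externally estimated) T1.  Magnitude data
  only, so the common TE decay factor cancels from the slope and T2 is
  unaffected by it.
* JSR: trust-region-reflective nonlinear least squares over (|M0|, ∠M0, T1,
  T2, Δω0); residuals are SPGR magnitudes plus real and imaginary bSSFP
  channels.  Initialization: T1, M0 from DESPOT1 on the SPGR subset, T2 at
  80 ms, Δω0 = 0; bounds T1∈[50 ms, 10 s], T2∈[5 ms, 5 s], |Δω0|·TR ≤ π;
  stopping at cost tolerance 1e-15 or 500 evaluations; one seeded perturbed
  restart if the final cost exceeds 1e-6·Σ|S|².  Δω0 is free by default
  (pinnable), and fixed to 0 when generating validation data, where no
  off-resonance is modelled.

Each estimator inverts its own noiseless forward model to ≤1e-6 relative.
Standard errors come from the linear-fit covariance (DESPOT, delta method for
T1/T2) or the Gauss-Newton J'J approximation at the optimum (JSR).

## Synthetic data and the Monte Carlo

The generator reproduces the numerical validation conditions: the
variable-flip-angle protocol (SPGR 6–16° in 2° steps; bSSFP
15/25/35/45/55/65° at Φ=π plus 25/55° at Φ=0; TR 7 ms; τRF 0.614 ms), pulsed
2-pool signals from the white-matter preset (M0f=1, M0m=0.157, kf=4.45 s⁻¹,
km=28.34 s⁻¹, R1f=1.1 s⁻¹, R1m=1 s⁻¹, R2f=12.3 s⁻¹, G=14 µs), and i.i.d.
Gaussian noise of SD 0.002·M0f on the real and imaginary channel of every
measurement.  CSMT sampling fixes the pulse energy at the 65° reference
(B1rms 2.05 µT, W̄ 13.2 s⁻¹, T1csmt 387 ms); non-CSMT scales energy with
flip².  The trial count defaults to 1000 (configurable; the reference studies
in the test-suite run 500, which resolves the effects while keeping the suite
fast).  What the generator does **not** emulate: off-resonance maps, RF
spoiling imperfection, finite-pulse effects on the free pool, Rician
floor at very low SNR, receive-coil shading, motion.  Passing tests therefore
demonstrate correctness of the models and estimators under the stated
conditions, not robustness to those real-world effects.

Known property worth flagging: at this noise level the linearized DESPOT1
T1 *mean* carries a +3% noise-induced bias (the correlated errors in both
regression coordinates lie along slope 1/cosα > E1), which is visible next to
the Monte Carlo standard error at n=500 even under CSMT sampling, where the
data are genuinely single-pool.  JSR means are unbiased to <0.2%.  The MT
signature — DESPOT/JSR disagreement and T2 underestimation — is an order of
magnitude larger under conventional sampling and vanishes to this noise-bias
floor under CSMT.

The digital phantom assigns a tissue preset per voxel with an optional smooth
B1+ map, and the voxelwise fitter accepts the same map for transmit
correction; region means recover the theory values within 2%.

## Numerical choices

* γ = 2.6752218744e8 rad s⁻¹ T⁻¹; SI units internally (T, s, rad); degrees,
  ms and µT only at the CLI and CSV boundary.
* Free-interval propagators by 5×5 augmented matrix exponential (exact affine
  map, identity at zero duration).
* Detailed balance is not assumed: presets with kf·m0f ≠ km·m0m (the
  white-matter values are ~0.01% off) relax toward the true fixed point of
  the exchange system, which differs from (m0_f, m0_m) in the fourth decimal.
* Degenerate designs (identical flips, single sequence type) raise;
  non-physical fit outcomes (slope outside (0,1)) are flagged in the result
  rather than raised, and are excluded from Monte Carlo summaries.
* Histogram plots use Freedman-Diaconis binning; plots are reporting
  artifacts only.

## Limitations

Single coherence pathway per sequence (ideal spoiling; no RF-spoiling phase
schedule realism), no finite-pulse free-pool effects, no slice-selective or
SMS pulse variants, frequency-independent G only, two pools only.  The
inversion-recovery observed rate is provided as the closed form; IR fitting
itself is out of scope.
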