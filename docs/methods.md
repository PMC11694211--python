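# Methods

## Coordinate frame and units

All analysis happens in a canonical frame: anteroposterior (AP) positive
**toward the lifter**, vertical positive up.  This makes the classic
optimal bar path literal: toward–away–toward reads
positive–negative–positive in (X1, X2, X3).  Marker files store
millimetres (motion-capture export convention) and are converted to metres
on read; an `AxisMap` reorders/sign-flips arbitrary lab frames into the
canonical one.  Reported displacements are centimetres, forces body-weight
multiples (BW), RFD BW·s⁻¹, power kW.  Gravity is 9.81 m·s⁻².

On the power/RFD unit choice: the source tables in this literature often
label these columns "W" and "N·s⁻¹" while printing magnitudes that are
only consistent with kW (force in newtons × bar velocity) and BW·s⁻¹
(sample-to-sample slope of BW-normalised force at 1 kHz, i.e. ΔvGRF/0.001
s).  We use those scales and label them honestly.

## Signal conditioning

* **Filtering** — 4th-order Butterworth, 4 Hz for marker trajectories and
  15 Hz for plate forces, applied forward and backward (`sosfiltfilt`).
  Zero-phase filtering was chosen so event timing is not lagged; the
  effective attenuation order doubles, and a sine at the cutoff emerges
  with amplitude ≈ 0.5.
* **Bar centre** — the per-sample mean of the two bar-end markers, which
  cancels antisymmetric artefacts of bar tilt.
* **Derivatives** — central differences (one-sided at the ends).
  Acceleration is the derivative of the derived velocity; each time
  derivative amplifies high-frequency error, which is why the kinematic
  cutoff is low and why Acc-max should be read with caution.
* **Body weight** — the mean summed vertical force of a ≥ 1 s quiet
  standing record (no barbell); the plate split is irrelevant.
* **Baselines** — signals are zeroed at the first recorded sample for
  storage, and all reported displacements and the 101-point normalised
  curves are re-zeroed at the detected movement start (the trimmed
  trajectory starts at exactly zero).
* **Time normalisation** — linear interpolation of the start→catch phase
  onto 101 points (0–100% of the movement), for curve export and
  visualisation only.  Discrete parameters are always extracted from the
  native-rate signals, because resampling would bias peak values.

## Events

* **Start**: first sample with vertical bar velocity ≥ 0.01 m·s⁻¹ that
  stays above threshold for 40 ms.  The sustain window is ours; a bare
  first-crossing rule triggers on single-sample noise.
* **Peak height**: argmax of vertical position after the start.
* **Catch**: first non-negative vertical velocity after the drop-under
  phase that follows peak height.  The drop-under phase is recognised
  once velocity falls below −0.05 m·s⁻¹; without that guard, sub-ripple
  sign flips right at the (zero-velocity) peak masquerade as catches on
  noisy data.
* **Takeoff** ("the jump"): first force sample below 5% body weight
  sustained 20 ms.  Absence of flight is a valid outcome; the until-jump
  windows then cover the whole movement and the row is flagged.

## AP landmarks (X1, X2, X3)

X1 and X2 are defined as stationary points of the AP path, not windowed
extrema, by an odd-symmetric rule:

* **X1** — the last stationary point of AP on (start, peak-height].  In a
  technically sound pull this is the toward-lifter excursion (X1 > 0).
  Beginners often drift the bar away and only partially recover; the
  recovery point is then a *negative* X1, matching the negative
  condition means reported for novice cohorts.  A strictly monotone pull
  has no stationary point; X1 then degenerates to the first post-start
  sample (≈ 0).  A windowed maximum cannot produce either behaviour: with
  the path zeroed at the start, max(AP) ≥ ≈ 0 always.
* **X2** — the largest-magnitude stationary point between the rearmost
  point and the catch (the turnover's away excursion), falling back to
  the most-away sample if the turnover is monotone.
* **X3** — AP position at the catch.  Stationary points need ≥ 1 mm
  prominence, which suppresses post-filter ripple.

The identities VTR = Y-max − Y-catch, DxV = X1 − X2, DxL = X3 − X2 and
DxT = X3 hold exactly by construction; they also reproduce the printed
condition means of the reference tables from their own components to
0.01 cm, which is what fixed the (otherwise prose-only) definitions of
DxV and DxL.

Classification: a path is optimal iff X1 > 0 ∧ X2 < 0 ∧ X3 > 0 (strict —
an exactly zero displacement is neither toward nor away); a subject
adheres in a condition iff all three repetitions are optimal.

## Statistics

Each variable is collapsed to a subjects × 4 table.  The unit of analysis
defaults to subject means over the three repetitions; trial-level units
are available via `PipelineConfig(stats_unit="trial")` (reference reports
in this area print denominator df consistent with trial-level units, so
both are supported).  The battery: Shapiro–Wilk per condition column at
α = 0.05, all must pass (a zero-variance column fails the gate); then
RM-ANOVA (statsmodels `AnovaRM`; partial η² = F·df₁/(F·df₁+df₂), which
equals SS꜀/(SS꜀+SSₑ)) or the Friedman test (mid-ranked ties; effect size
Kendall's W = χ²/(n(k−1))).  Post hocs run only on a significant omnibus:
all six pairs, paired t after ANOVA or Wilcoxon signed-rank (Pratt
zero-handling) after Friedman, Bonferroni ×6 capped at 1.  Degenerate
tables: identical columns give F = 0 (no condition effect); a wholly
constant table raises.

**Power**: within-factor RM-ANOVA power is P[F′(df₁, df₂, λ) > F₍crit₎]
with λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε; ε = 1
(sphericity) by default, matching the common a-priori software default.
At f = 0.5, α = 0.05, m = 4, ρ = 0.5 this gives power 0.9510 at n = 10,
and n = 10 is the smallest size reaching 0.95 (power(9) = 0.9216).  A
200,000-trial Monte Carlo of the RM-ANOVA under compound symmetry in the
test suite confirms the formula to within simulation error.

## Synthetic data

The generator emulates the measurement setup (two bar-end markers at
250 Hz ± optional antisymmetric offsets that cancel in the mean; two
plates at 1000 Hz with a smoothly varying left/right split) from
programmable per-trial truth: Y-max, Y-catch, X1, X2, X3, V-max, movement
duration, peak vGRF, flight onset, body/bar mass, and per-channel
Gaussian sensor noise.  Defaults sit at the magnitudes typical of novice
power-snatch cohorts (Y-max ≈ 161 cm, X2 ≈ −17 cm, V-max ≈ 3.15 m·s⁻¹,
duration ≈ 1.3 s, peak force ≈ 2.55 BW, 20 kg bar).

Design choices that make the programmed values *true*:

* The vertical rise is a quintic smoothstep whose peak slope is exactly
  V-max; the descent is a single smoothstep spanning the whole post-peak
  movement (interior velocity strictly negative — no flat pockets for
  noise to flip) ending in a ≈ 1.5 cm dip-and-rebound whose minimum is
  the catch, giving the event a transversal velocity zero crossing as in
  real lifts.
* The AP path is piecewise quintic smoothsteps between landmarks, with an
  early away-drift dip inserted when X1 ≤ 0 so the programmed value is a
  genuine recovery point.
* Both paths are emitted 4 Hz band-limited (human bar motion is smooth),
  and the landmark amplitudes are re-anchored by a three-step fixed-point
  correction against the measurement chain's view (the analysis low-pass
  applied to the emitted signal), so programmed landmarks are what a
  standard 4 Hz pipeline reads.  Without re-anchoring, filter ringing on
  spline corners biases landmarks by up to ≈ 1 cm.
* The force profile is a two-mass surrogate, not a simulation: baseline
  (body+bar) weight, a cos² pull peak reaching the programmed maximum, an
  unweighting dip, a 45 ms ramp to zero ending at the programmed flight
  onset (so the 15 Hz-filtered trace crosses the 5% BW threshold at the
  onset), a 120 ms flight, and a landing bump constrained below the pull
  peak.  A stationary pre-lift window means the summed plates integrate
  to (body+bar) weight.

The cohort layer draws each parameter hierarchically: subject effect
(SD = √ICC·σ, shared across conditions), condition-cell effect
(SD = √(1−ICC)·σ), trial noise (0.35σ), with ICC = 0.5 by default —
the repeated-measures correlation assumed in the power analysis — and σ
taken from the between-subject spreads of published novice cohorts.
Per-condition mean shifts are all zero by default (the global null,
matching the reported null results); `condition_shifts` plants effects.
Draws are clipped to physically realisable ranges (e.g. VTR ≥ 8 cm,
duration long enough for the rise at V-max plus a ≥ 0.3 s drop-under);
clipping is identical across conditions, so null-calibration is
unaffected.

What the generator does **not** emulate: marker occlusion/gaps, soft-
tissue or impact artefacts, plate drift, asymmetric left/right loading
dynamics, inter-segment coordination, or any learning process (conditions
differ only through planted feature shifts).  Passing tests therefore
show the *pipeline* is correct and calibrated on in-distribution signals,
not that the physiological conclusions transfer to any particular lab's
recordings.

## Numerical choices and degenerate inputs

* Filter warm-up requires ≥ 3·(order+1) samples; shorter series raise
  with the minimum stated.
* Velocity is linearly interpolated onto the 1 kHz force grid for the
  power series; the RFD definition (ΔvGRF per 0.001 s) fixes the force
  grid as primary for kinetics.
* The until-jump mean RFD is naturally *negative*: the window ends at
  takeoff where the force has unloaded from ≈ 1 BW to ≈ 0, so the mean
  slope is ≈ −(1 BW)/(time to takeoff).  Published tables showing
  negative until-jump mean RFD are consistent with this reading.
* Wilcoxon uses Pratt zero-handling; identical pairs get p = 1.
* `min_sample_size` searches n upward from 2 and is the exact argmin
  (power(n−1) < target ≤ power(n)).

## Problem sizes used in the test suite

Unit and property tests run on single trials and 3–16-unit tables; the
calibration checks use 2000 i.i.d.-normal tables (battery size) and 500
simulated cohort tables (null rejection rate), and parameter recovery
sweeps 50 noiseless cohort draws — sizes chosen to give standard errors
well inside the asserted bands while keeping the default suite fast.

## Known limitations

* Acc-max inherits double-differentiation noise amplification; treat it
  qualitatively.
* The X1/X2 stationary-point rule needs ≥ 1 mm prominence; excursions
  smaller than that degenerate to near-zero values.
* No sphericity correction is applied in the omnibus RM-ANOVA (reference
  reports print uncorrected df); ε enters only the power computation.
* C3D input is not supported; the documented TSV dialect is the reference
  interchange format.
* The kinematic and force streams are assumed to start simultaneously; an
  integer `force_offset` per manifest entry is provided for known
  misalignment, but no automatic synchronisation is attempted.
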