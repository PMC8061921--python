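# Methods

## Geometry and units

All conversions between volumetric flow and mean velocity use the
volumetric-flow relation v = Q / A with A = π d² / 4 over the **nominal**
(non-stenotic) inner diameter, including for stenotic settings: the field
of view sits in the laminar region away from the stenosis insert, where
the full lumen carries the flow.  The public API uses the units of the
experiment's instruments — mm (diameters), ml/min (flows), cm/s
(velocities) — and converts internally in cm–s units; the conversion
functions are exact inverses of each other to machine precision.

The longitudinal FOV size *s* entering the FDHM formula defaults to
22.4 mm (the drive-field extent) but is configurable; because the
correction factor *c* is calibrated as a ratio against ground truth, a
different constant choice of *s* rescales *c* and leaves every calibrated
velocity unchanged.

The four-setting registry (rest 4 mm at 151 ml/min, healthy hyperaemia
6 mm at 680 ml/min, stenotic hyperaemia 205 ml/min, doubled-power
stenotic 410 ml/min, each with its flow-meter uncertainty) ships as a
YAML fixture and is user-replaceable.

## Synthetic bolus model

The simulator uses the minimal transport physics consistent with a
dispersed, advected bolus: a 1-D Gaussian advection–dispersion kernel

    phi(x, t) = exp(−(x − x₀ − v t)² / (4 D (t + t₀))) / sqrt(4 π D (t + t₀))

with x₀ = −run_in_distance and t₀ = run_in_distance / v, so the bolus
enters the FOV already broadened by the dispersion accumulated over the
25 cm between injection site and FOV.  The noiseless frame-summed signal
is baseline_level plus injected_amount times the tracer fraction inside
[0, s], evaluated in closed erf form.  The 4D renderer distributes each
longitudinal slice's signal uniformly over the lumen cross-section voxels
(cylinder mask on a 28×28×14 grid of 1 mm voxels, frame interval
21.54 ms) and clips the sensitive length to the FOV, so the noiseless
frame sum of a rendered stack equals the closed-form curve exactly.

Defaults and rationale:

- **velocity**: per-setting, drawn per bolus by jittering the setting's
  flow with the flow-meter uncertainty (truncated at 10 % of nominal),
  then converting through the nominal diameter — each simulated
  measurement has its own known true velocity, as each real measurement
  has its own flow-meter reading.
- **dispersion D = 0.1 cm²/s**: no dispersion value is reported for the
  experiment.  With constant D the bolus reaches the FOV with a FWHM
  around 1 cm over the coronary range (12–64 cm/s), so the transit
  duration is dominated by the FOV length; this keeps the per-tube FDHM
  correction factor approximately velocity-independent (coefficient of
  variation ≈ 7 % across 20–64 cm/s), the property that justifies using
  a single per-tube factor and that the real series exhibit (CV ≈ 3–7 %).
  The absolute factor magnitude is *not* matched: the experimental
  factors (c ≈ 11–26) imply boluses dispersed over tens of centimetres,
  which a velocity-independent-D model cannot reproduce simultaneously
  with a constant c; the calibration step absorbs this scale by design.
- **noise**: additive i.i.d. Gaussian, sd 1.0 per frame on curves
  (peak signal ≈ 70–95 with the default injected amount of 100, i.e.
  SNR well above the QC floor of 5), or per voxel on stacks.  The
  experiment reports no SNR; these levels keep QC behaviour realistic
  without modelling the reconstruction noise spectrum.
- **seeds**: one series seed; per-bolus seeds are seed + index.

Ground truth (FDHM, AUC, peak time) is computed by an independent oracle:
dense evaluation of the closed-form signal on a grid 200× finer than the
frame interval with linear crossing refinement, never by the estimator
code paths it is used to validate.

What the simulator deliberately does not emulate: the imaging physics and
reconstruction (harmonics, system function, regularization artefacts),
turbulent jets and recirculation at the stenosis, pulsatile flow, tracer
sedimentation at low velocity, and the very large injection-driven
dispersion of the real experiment.  Passing recovery tests therefore
demonstrates the correctness and statistical behaviour of the *analysis
chain*, not scanner-level performance.

## Curve processing

Order of operations: frame sum → linear interpolation (×10) → baseline
estimation → subtraction → quality control → estimators.

- **Interpolation** is piecewise linear with exact node preservation;
  factor 10 refines the 21.54 ms frames to ≈ 2.15 ms, the resolution at
  which half-maximum crossings are then refined linearly once more.
- **Baseline window auto-detection**: the reference method for the
  experiment's baseline determination is not described, so the package
  uses a robust substitute: the level and spread (median, 1.4826·MAD) of
  the first 10 % of samples define a 4-sigma band, and the window is the
  longest initial run staying inside it.  A manual window can always be
  supplied; a window containing a genuine peak (one exceeding the
  window's own 4-MAD band) is rejected.
- **Idempotent subtraction**: baseline state is recorded on the curve;
  subtracting twice is a no-op by construction rather than by
  re-estimation.
- **Quality control** passes a curve when (i) exactly one local maximum
  exceeds half the global maximum after smoothing with a moving average
  one original frame wide — with a prominence floor of 5 % of the
  amplitude so that residual noise ripples on the smoothed peak do not
  count as separate maxima; (ii) the amplitude exceeds 5× the
  baseline-window noise sd; (iii) the signal returns below 33 % of
  maximum before the record ends (otherwise the transit is truncated).

## Estimators

- **FDHM** uses the contiguous half-maximum interval around the global
  peak, each crossing refined by linear interpolation between the
  bracketing samples.  QC guarantees a single dominant peak, so this
  coincides with the union-of-intervals definition on accepted curves;
  ties at the maximum resolve to the earliest sample.
- **AUC** starts where the baseline-subtracted curve first rises to the
  baseline mean (equivalently, raw signal at twice baseline — the onset
  multiple is configurable because the prose definition admits more than
  one reading) and ends at the first post-peak decline to 33 % of
  maximum.  Integration is trapezoidal on the interpolated grid with the
  exact crossing times inserted as boundary points.
- ε, the tracer-dilution factor, is stored as a plain number whose
  composite unit makes v come out in cm/s for AUC in a.u.·s; no attempt
  is made to match the experimentally printed magnitudes, whose printed
  unit (ml) is dimensionally incomplete.
- The modified Bernoulli conversion Δp = 4 v² (v in m/s, Δp in mmHg) is
  provided for translating jet velocities into pressure gradients.

## Calibration

Intrinsic factors invert the velocity formulas against per-measurement
ground truth: c = v_ref · FDHM / s, ε = v_ref · A · AUC.  Leave-one-out
calibration assigns measurement *i* the mean of the complementary
factors and, as error, their standard error of the mean (sd with n−1
denominator over the n−1 complementary factors), both propagated through
the measurement's own kernel (s/FDHM or 1/(A·AUC)).  The mean of the
leave-one-out factors equals the mean of the intrinsic factors exactly —
an algebraic identity asserted at 1e−12 in the tests.

Interpretation of the published stenosis table was fixed by
back-calculation: the printed per-measurement "correction factor" is the
leave-one-out mean (not the measurement's own ratio) and the printed
velocity is that factor times the raw kernel; this is the only reading
consistent with all three doubled-flow-setting rows simultaneously
(reproduced within ±0.03).  Transfer between series uses the unweighted
mean of the source series' intrinsic factors.  No outlier rule is
applied by default; the published overall error "cleaned for outliers"
is not operationalized anywhere and is therefore not reproduced.

## CFR/FFR and agreement

Image-derived CFR/FFR use the mean calibrated velocity of a stenotic
series converted to flow through the nominal 6 mm cross-section,
referenced against the flow-meter flows of the rest (Q_norm) and healthy
hyperaemia (Q_max) settings.  Ratios are kept at full precision
internally and rounded to 2 d.p. only in table-mirroring output.
Agreement uses Pearson correlation with a two-sided t-test p-value
(reported, never used as a gate) plus the mean absolute relative error.

## Problem sizes and determinism

The test suite and the acceptance script simulate 6 boluses per setting
(matching the deepest real series) with curves of a few hundred frames;
the whole suite runs in a few seconds.  All randomness flows from
explicit seeds; repeated runs with the same seed are bit-identical.

## Known limitations

- The constant-D dispersion model cannot reproduce the absolute
  magnitude of the experimental correction factors (see above); only
  their relative constancy and the calibration mechanics are emulated.
- At the top of the velocity range (≳ 60 cm/s) a transit spans only ~2
  frames and FDHM becomes sampling-limited, mirroring the real
  motivation for curve interpolation; estimator-vs-oracle agreement
  within one refined step is therefore asserted at the four canonical
  setting velocities (12–40 cm/s).
- Tracer-dilution calibration is implemented and tested, but the CFR
  experiment defaults to FDHM, which the underlying study found clearly
  superior.
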