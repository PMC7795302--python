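# Methods

This note records the modelling assumptions, the defaults that matter, the
design choices made where the underlying method leaves the design open,
and what the synthetic-data validation does and does not demonstrate.

## Data model

A session holds one recording per exercise: 21 facial points of interest
(POI) in 3D at a variable sampling rate (units to tens of Hz), so a
complete session carries 3 × 21 × 9 = 567 scalar time curves. Units are
seconds and meters, but every downstream indicator is a ratio of
distances, so the pipeline is unit- and frame-agnostic up to rigid motion
and uniform scale. Timestamps may be irregular; nothing is resampled at
ingest — interpolation happens once, at registration.

Raw House–Brackmann grades 4 and 5 are rare and clinically adjacent to 3
and 6; they are merged (4→3, 5→6) before any modelling, leaving the four
adjusted levels (1, 2, 3, 6). Outlier exclusion is a human decision
recorded as a manifest flag; the pipeline warns on suspicious sessions but
never excludes on its own.

## Stage 1 — registration

* **Alignment curve.** Raising/Frowning: sum of the left (POI 4–2) and
  right (10–8) eyebrow-to-inner-eye-corner distances; Smiling, Baring,
  Pursing: the mouth-corner distance (14–15). Including both halves keeps
  one-sided movers registrable.
* **Orientation.** For Pursing and Frowning the alignment distance
  *shrinks* during activity. After min-max normalization the curve is
  inverted when its median exceeds 0.5 (rest dominates the timeline, so
  the median sits at the rest level); activity then always points upward
  for template matching.
* **Smoothing.** Centered moving average, window 5 samples (odd, truncated
  at the ends); Savitzky–Golay is available. The window is in samples, so
  at low sampling rates it spans more real time — the landmark fallback
  below absorbs the resulting bump smearing.
* **Repetition count.** DTW (symmetric steps, squared-difference cost)
  between the normalized curve (downsampled to ≤150 points) and
  rest–bump templates with k = 2, 3, 4 raised-cosine bumps (10% lead/trail
  rest, inter-bump gaps half a bump width — the template geometry is a
  package convention; the matching is warp-invariant so only the bump
  count matters). The distance is divided by the optimal path length;
  ties break toward k = 3, the instructed count. A constant curve raises a
  flat-signal error.
* **Landmarks.** Each template bump's support is mapped through the DTW
  path to a span of curve samples; from the span's peak the curve is
  walked outward to the 0.15-of-range activation threshold crossing
  (linearly interpolated between samples). If noise keeps the curve above
  threshold inside an inter-bump gap, the landmark falls back to the
  valley between the matched bumps. 2k strictly increasing landmark times
  result.
* **Warping.** Shape-preserving piecewise-cubic Hermite interpolation
  (Fritsch–Carlson slopes) through (reference landmark, sample landmark)
  pairs — monotone by construction where a plain cubic spline need not
  be — extended linearly outside the knots with the end-interval secant
  slopes. Reference landmarks are the template bumps' own threshold
  crossings on [0, 1]. One warping per session-exercise, computed from the
  alignment curve and applied to all 63 coordinate curves (linear
  interpolation at the warped instants, clamped to the recorded span),
  onto a 100-point reference grid.
* **Repetition selection.** The second repetition (the first and last are
  most often corrupted by startup/fatigue noise). Its window is extended
  to the midpoints toward the neighbouring repetitions and re-interpolated
  onto a fresh 100-point grid renormalized to [0, 1]; this keeps sessions
  with different repetition counts on one common grid, which the
  functional regression requires.

## Stage 1 output — indicators

Fourteen labelled curves: symmetry/intensity/speed for Raising
(`eyebrows.*`), Frowning (`frowning.*`), Smiling (`smiling.*`), Baring
(`teeth.*`), and intensity/speed for Pursing (`lips.*`). Symmetry compares
inner-eyebrow-to-inner-eye-corner distances for the brow exercises and
mouth-corner-to-outer-eye-corner distances for Smiling/Baring (eye corners
are the most stable reference points). Intensities are signed — motion
that shrinks a distance goes negative — and are exactly 0 at baseline.
Baseline distances v(0) default to the mean of the first five grid points
of the selected repetition's rest margin (damps sensor noise); a strict
first-sample mode matches the formulas literally. The speed indicator is
the warping function rescaled to the unit square, in the *measured-time*
parametrization (aligned time as a function of measured time): a patient
who rushes through the exercise produces a curve above the diagonal early
on — the convention under which brisk execution is "steep at the
beginning". Missing or failed exercises yield flagged absences, never
fatal errors.

## Stage 2 — health scores

One penalized functional logistic regression per indicator label. β(t) is
expanded in a cubic B-spline basis (dimension 8 on [0, 1]); ∫X(t)β(t)dt is
evaluated by trapezoid quadrature on the common grid; the intercept is
unpenalized and the basis coefficients carry a ridge penalty (default
1e-3). The penalty matters: with ~tens of curves per extreme group and a
rich functional covariate, the Healthy/Sick groups are routinely linearly
separable and the unpenalized MLE diverges; separation is detected and
reported. Training uses adjusted grades (Healthy = 1, Sick = 6) and the
fitted model scores *every* session, so intermediate grades land at
intermediate scores. Speed curves enter as warping-minus-identity
residuals by default, removing the deterministic diagonal trend that
would otherwise dominate the basis expansion.

Diagnostics: Spearman rank correlation (mid-rank ties, two-sided t
approximation) of each label's scores against the grade, and the pairwise
Pearson correlogram of scores across labels (pairwise-complete, unit
diagonal).

## Stage 3 — ordinal classification

Proportional odds exactly — the slopes β_i are level-independent; no
partial-odds extension. Thresholds are parametrized as α_1 plus log-gaps,
which enforces their ordering unconditionally. The negative weighted
log-likelihood is minimized by L-BFGS-B with an analytic gradient
(tolerance 1e-8, ≤500 iterations); standard errors come from a
finite-difference observed information at the optimum. Session weights are
1/count(class); inside the fit they are rescaled to mean 1 — the ML fit is
invariant to the overall weight scale, and the rescaling keeps the
log-likelihood (hence AIC) on the usual per-observation scale so the
2-per-parameter AIC penalty is commensurable with likelihood gains,
matching the effective behaviour of R-style stepwise selection with
frequency weights. Stepwise selection is greedy and bidirectional from the
empty model: at each step the single add-or-drop move with the largest AIC
reduction is applied; candidate fits that fail are skipped with a warning.
Training uses complete cases (all candidate scores present) so AICs are
comparable across moves. "Approximate" classification means |predicted −
true| ≤ 1 on the numeric grade values, so 3 vs 6 is not approximate;
display percentages are rounded to integers with exact fractions retained.
Argmax ties resolve to the lower (healthier) grade.

## Synthetic cohort generator

The generator emulates what the pipeline assumes about real sessions:

* a bilaterally symmetric neutral face (left/right homologues mirror
  about x = 0);
* per indicator-bearing exercise a fixed displacement field (eyebrows up
  for Raising, mouth corners in for Pursing, mouth ellipse opening for
  Baring, …) driven by rest – k raised-cosine bumps – rest activation,
  k ∈ {2, 3, 4};
* paresis as (i) *attenuation* of the affected half's displacement,
  (ii) a global range-of-motion multiplier, (iii) a one-parameter monotone
  power distortion u ↦ u^γ of normalized time (γ < 1 front-loads the
  exercise — brisk, healthy onset);
* a per-session sampling rate drawn from 8–30 Hz and i.i.d. Gaussian
  coordinate noise (default sd 0.5 mm).

Grade defaults: attenuation 1.0 / 0.8 / 0.5 / 0.05 and intensity scale
1.0 / 0.95 / 0.85 / 0.7 for adjusted grades 1 / 2 / 3 / 6, with small
per-session jitter. The intensity decline is deliberately milder than the
attenuation decline: the asymmetric amplitude scales as
intensity × (1 − attenuation), and a steep intensity drop for bad grades
would cancel precisely the grade-3 vs grade-6 asymmetry contrast that the
symmetry indicators (and the clinical picture of one-sided paralysis)
rely on. Speed defaults γ = 0.7 / 0.85 / 1.0 / 1.3. The default class mix
(58, 21, 23, 20)/122 mirrors a realistic rehabilitation cohort.

Ground-truth landmark times are defined as the activation's
0.15-threshold crossing instants (closed form from the raised cosine,
mapped through the speed distortion) — the same threshold the extractor
uses, so recovery is measured apples-to-apples.

**What passing synthetic tests does not show.** The generator has no
synkinesis, no tracking dropouts, no autocorrelated or
landmark-correlated sensor error, no within-session fatigue drift, and
its activation waveform is idealized; depth-camera face trackers also
tend to place landmarks more symmetrically than severely paretic faces
really are, an acquisition bias no algorithm downstream can undo.
End-to-end classification accuracy on synthetic cohorts (≳ 90 % correct at
the defaults) therefore overstates what the same pipeline achieves on
clinical data (about 60 % correct, 86 % within one grade); the synthetic
figures validate the machinery, not the clinical effect size.

## Numerical choices and degenerate inputs

* DTW local cost is the squared difference; the kernel is numba-jitted
  with a pure-Python fallback, and correctness is pinned to brute-force
  path enumeration on short sequences.
* Logistic likelihoods use log1p/softplus-stable forms; probabilities are
  clipped at 1e-300 before logs.
* Zero distances (coincident landmarks) raise degenerate-geometry errors
  rather than producing infinite ratios; constant alignment curves raise
  flat-signal errors; one-class training sets raise explicit errors.
* All simulation, fitting and pipeline entry points are deterministic
  given a seed; CLI reruns with identical seed and configuration are
  byte-identical.

## Problem sizes used in validation

The shipped validation uses 120-session cohorts for the end-to-end check,
30 noiseless + 50 noisy sessions for registration recovery, 20 replicates
of n = 500 for proportional-odds coverage and 5 replicates of n = 200 for
stepwise selection — sizes at which every Monte-Carlo margin in the suite
is comfortably resolved while the whole suite stays fast on one CPU.

## Known limitations

* The four unscored exercises (Closing, Blowing, both combined) travel
  through the data model but produce no indicators.
* The health-score stage assumes a common registered grid; sessions whose
  registration failed for an exercise simply lack those scores.
* AIC-based stepwise selection admits a pure-noise covariate with
  probability ≈ 0.16 per candidate comparison (χ²₁ > 2); on small
  candidate sets an occasional marginal inclusion is expected behaviour,
  not a defect.
* No cross-validation: models are fitted and assessed in-sample by
  design; predictive model assessment is out of scope.
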