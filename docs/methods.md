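# Methods

This note documents the models, conventions and numerical choices behind
`iconqa`, and what the synthetic-data tests do and do not demonstrate about
clinical data.

## Coordinate and data conventions

All geometry lives in the Leksell stereotactic frame, in millimetres, with
the radiological focus nominally at (100, 100, 100). Displacements are signed
differences in this frame; no axis re-mapping is applied. Rotations are
stored as 3×3 proper orthonormal matrices and exchanged as Euler angles in
degrees with z-y-x composition (`R = Rz·Ry·Rx`), the convention under which
clinical systems report rotational corrections.

Motion logs use a CSV dialect with `# key: value` metadata (session id,
gating threshold, record trigger, window) followed by
`t_s,x_mm,y_mm,z_mm,radial_mm,state,event` rows. Two properties of the
clinical recording are preserved deliberately:

* `radial_mm` is the **trailing-window mean** radial displacement (not
  centered — the record describes the last window), while `x/y/z` are
  **instantaneous** values from the end of that window. The norm of
  (x, y, z) therefore disagrees with the recorded radial in general, and the
  parser must not reconcile them. Signed per-axis statistics always use
  x/y/z; radial statistics always use the recorded radial; they are never
  mixed.
* Each `baseline`/`rebaseline` row carries the residual displacement left
  after an image-guidance correction; subsequent rows are relative to that
  new baseline. The gating threshold is read per session from the log
  header rather than assumed globally, since providers may configure it.

## Truncated AUC mean displacement

The mean position over a treatment segment is the time-weighted average of
the piecewise-linear record over **treating** intervals only. Paused
intervals are excluded from both the numerator and the denominator: no dose
is delivered while paused, so those excursions carry no weight. A sample's
state holds until the next sample, so an interval spanning a state change is
attributed to its left endpoint's state — state changes occur exactly at
record timestamps, where the recorder always emits a row.

The radial curve is truncated at the gating threshold before integration
(delivery pauses beyond it, so larger recorded values cannot correspond to
delivered dose). Truncation is implemented as **exact integration of the
pointwise-clipped piecewise-linear function**: within each interval the
integral of `min(linear, threshold)` is evaluated in closed form, including
the crossing point when the segment straddles the threshold. Clipping only
the endpoint values would make the result depend on the sampling density;
the closed form makes the statistic exactly invariant under refinement of
the same piecewise-linear trace, which the property tests assert at 1e-12
and an independent refined-grid trapezoidal oracle confirms at 1e-9. The
trapezoidal rule (rather than anything higher-order) is the natural choice:
the record *is* piecewise linear, so trapezoids are exact for it.

An all-paused segment yields an empty result (`None`), not an exception — a
session in which the patient never settled is a valid, empty observation.
Multi-segment sessions are aggregated with treating-time weights.

## Cohort statistics and the vector-mean convention

Per-session AUC means are summarized across patients into budget rows:
per-axis mean ± sample SD of the signed means, and vector mean ± SD of the
per-session radial means. The **vector mean is always the mean of
per-measurement magnitudes**, never the norm of the axis-wise means; by the
triangle inequality it dominates the latter, and the two differ strongly
whenever motion is unbiased but non-zero. Post-image-guidance residuals are
pooled over all baseline events and summarized the same way, using each
event's *recorded* radial as its magnitude (consistent with the
windowed-vs-instantaneous distinction above).

## Quadrature budget

Components are classified systematic or random, and Type A (own repeated
measurements) or Type B (published/manufacturer data; MRI distortion is the
only Type B row in the bundled table). Totals are root-sum-squares under
independence and normality, per axis and for vector means; the combined row
equals the quadrature of the systematic and random rows by associativity.
Numerical conventions:

* **Absent axis entries are excluded, not zero-filled.** A radial-only
  device (the CBCT daily-stability check) contributes to the vector total
  but carries no per-axis information; treating absence as 0 would be a
  claim of perfect accuracy. The bundled table's printed x total is
  reproduced only under exclusion.
* Signed axis means enter through their squares; totals are reported
  unsigned, as is conventional.
* **Total vector SDs are reported as not derivable (NaN) for summary-only
  input.** The bundled table's printed total vector SDs (0.64/0.40/0.51 mm)
  match neither the quadrature of component vector SDs nor of axis SDs; with
  only row summaries there is no defensible formula, so the package computes
  a vector SD only from raw per-measurement vectors and otherwise takes the
  printed value as an explicit input (e.g. for the probability model).
* The bundled table adopts the tabulated MRI–CBCT registration x-mean of
  0.01 mm; an alternative reported value of 0.13 mm is inconsistent with the
  tabulated x totals, and the preset logs a warning documenting the choice.
* Report display rounds to 2 decimals, half-up; numerical comparisons in
  tests use ±0.015 mm, the two-decimal rounding band.

**Sub-threshold probability.** Treating the combined total as
`N(mean, sd)`, `prob_below(d, mean, sd) = Φ((d − mean)/sd)`, with a step
function at the mean when `sd = 0`. With the bundled inputs (1.30, 0.51)
the probability of staying within 1.00 mm is 0.278.

**Setup margins.** `margin = a·Σ + b·σ` with (a, b) = (2.5, 0.7) for the
van Herk population recipe and (2.0, 0.7) for Stroom. The pipeline applies
the recipes per axis using the combined per-axis systematic/random SDs;
coefficients live in configuration, not code.

## Synthetic motion model and study conditions

The generator emulates, per session, marker motion as **per-axis linear
drift plus a Gaussian random walk** on top of a constant baseline offset
(the post-correction residual). This is the simplest model that reproduces
the qualitative clinical pattern — slow superior (z-dominant) drift with
small jitter — while keeping every parameter interpretable:

| parameter | default | meaning |
| --- | --- | --- |
| `duration_range_s` | 384–6468 s | session lengths, uniform (6.4–107.8 min) |
| `sample_interval_ms` | 100 | raw tracking rate beneath the window (the true camera rate is not publicly specified; exposed as a parameter) |
| `drift_mean/sd_mm_per_min` | (0, −0.001, 0.005) ± (0.003, 0.003, 0.006) | per-session drift velocity distribution, z-dominant |
| `walk_sigma_mm` | (0.002, 0.002, 0.003) | random-walk step SD per sample |
| `residual_mean/sd_mm` | (−0.02, −0.02, 0.11) ± (0.17, 0.21, 0.37) | post-correction residual distribution (clinical values) |
| gating | 1.5 / 0.2 / 500 | threshold mm / record trigger mm / window ms |

Drift and walk scales were calibrated once so a default 30-session cohort
has a dense-truth mean radial AUC of ≈ 0.7 mm with the largest signed
component in z, matching the clinical cohort the defaults emulate; they are
parameters, not constants.

The **recorder** turns a dense trace into a log exactly as the analysis
assumes the clinical system behaves: windowed radial, instantaneous axes, a
record whenever the windowed radial moves more than the trigger from the
last *emitted* record (pure change-from-baseline would re-trigger every
sample during any sustained offset; hysteresis reproduces the "one record
per 0.2 mm step" behaviour), a forced record at every treating/paused
transition so pauses are visible to the integrator, and baseline/end rows.
The simulator flags pauses but does not model couch retraction or
re-imaging; re-baselining is an explicit log event, not a simulated process.

What passing the synthetic tests shows: the full chain — logging rules,
parsing, segmentation, truncation, time weighting, cohort summary — recovers
injected ground truth within sampling error (3 standard errors on a
30-session cohort), and the budget arithmetic reproduces a published totals
table from its component rows. What it does not show: that real patient
motion follows a drift+walk process (real traces have respiratory/cardiac
structure, mask relaxation, and nose-vs-skull decoupling the marker cannot
see), nor that the printed component values transfer to another clinic.
Record sparsification (the 0.2 mm trigger) biases the log-based AUC slightly
relative to dense truth — about 0.02–0.03 mm on the default conditions, well
inside cohort sampling error, but visible in the recovery tests' margins.

Fixtures that stand in for unavailable clinical measurements are labelled
synthetic: the readout-accuracy fixture (36 quantized 0.01 mm-resolution
single-axis moves whose summary rounds to the published row) and the
stationary-phantom log (baseline residual −0.09, 0.06, 0.06 mm with recorded
radial 0.09 mm, preserving the radial-vs-norm asymmetry).

## Known limitations

* Components are assumed uncorrelated and normal; quadrature is a
  conservative convention, not a verified error model.
* A single nose marker cannot distinguish head rotation from translation;
  target uncertainty is taken equal to marker displacement, which over- or
  under-states it depending on rotation axis.
* TRE is computed from exactly matched labels (no point-matching search) and
  the package evaluates registrations from points only — no image-intensity
  registration.
* The probability and margin models inherit whatever SD they are given; for
  summary-only budgets that SD is an input, not a derived quantity.
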