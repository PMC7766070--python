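# Methods

## Problem and model

Uterine electrical activity recorded on the maternal abdomen
(electrohysterogram, EHG) spreads as waves of surface potential.  This
package estimates the conduction-velocity amplitude and propagation
direction of those waves from four bipolar signals measured on a square
electrode grid of side `d = 7 cm` (E2 top-left, E1 top-right, E3
bottom-left, E4 bottom-right), and aggregates them into per-interval
features used to separate preterm from term records.

The wave is modelled as planar and locally linear: within one short
analysis step it crosses the array with a fixed velocity amplitude `CV`
and incidence angle `φ` measured from the vertical axis (`φ = 0` is
downward/south, `φ = 90°` rightward/east).  Under that model the
top-pair and bottom-pair bipolar signals (S1, S3) are time-shifted
copies of one another, with the shift equal to the vertical transitional
time `t_V = d·cos φ / CV`; likewise the left/right pair (S2, S4) is
shifted by `t_H = d·sin φ / CV`.  Then

    CV = d / √(t_V² + t_H²),      φ = atan2(t_H, t_V),

with the quadrant of `φ` resolved by the signs of the two transitional
times (a two-quadrant arctangent cannot populate all four sectors).
Angles map to half-open sectors: south `[−45°, 45°)`, east
`[45°, 135°)`, north `[135°, 180°) ∪ [−180°, −135°)`, west
`[−135°, −45°)`; south/north are the vertical direction, east/west the
horizontal one.

Only three bipolar signals are recorded; the fourth follows exactly
from the electrode potentials: `S4 = E4 − E1 = S1 − S2 + S3`.  S3 and
S4 are multiplied by −1 so that each correlated pair is equally
oriented (their dipole axes point the same way); without this the
correlation peaks at the wrong extremum.

## Estimation procedure

1. **Wide-band filter** S1–S3 at 0.08–5.0 Hz, derive S4, then filter
   all four signals in the analysis band.  Filters are fourth-order
   Butterworth band-passes applied forward-backward (zero phase,
   doubled roll-off, odd-reflection padding).  Bands: B0′ 0.3–1.0 Hz
   (contraction mechanism), Bb 0.3–4.0 Hz, and B1 1.0–2.2, B2 2.2–3.5,
   B3 3.5–5.0 Hz (maternal heart-rate influence and harmonics).
   Because filtering is linear, deriving S4 before or after the
   per-band filter is equivalent; the tests assert this rather than
   assume it.
2. **Short-time cross-correlation.**  A correlation window of
   `w_C = 5 s` is evaluated every `d_CI = 0.5 s`, starting at
   `w_C / 2`; windows that would overrun a record edge are omitted
   (zero-padding would bias shifts toward 0).  A 30-min record yields
   (1800 − 5)/0.5 + 1 = 3591 estimates.  Within each window both
   signals of a pair are min-max normalized to [0, 1] (no mean
   removal), and the lag maximizing `C(m) = Σ x(n)·y(n−m)` within
   `±d_SS = ±1 s` (±20 samples at 20 Hz) is the similarity shift.
   Transitional times are `t = −s/fs`; positive vertical shift means
   upward travel, positive horizontal shift rightward travel.
3. **Validity rules.**  Both shifts zero → no propagation (`CV = 0`,
   `φ` undefined).  `CV > 30 cm/s` → physiologically implausible
   outlier, also zeroed.  A constant (degenerate) window has no
   measurable lag and contributes zero transitional time.

### Numerical choices

* **Full-overlap lag search.**  The correlation sum is written with
  infinite support, so the second signal's window is cut `d_SS` wider
  on each side and every searched lag uses the full `w_C`-worth of
  products.  This matters because the [0, 1] normalization leaves a
  positive offset: with zero-padded equal windows the offset adds a
  triangular term peaked at lag 0 that can alias the argmax toward
  zero by whole carrier periods.  With full overlap the offset term is
  flat and the argmax sits on the true lag.  At record edges the
  extension is zero-filled so the center tiling is unchanged.
* **Tie-breaking** at the correlation argmax: smallest `|m|` wins,
  then negative `m` — ambiguity resolves toward "no propagation"
  rather than a spurious fast wave.
* **Integer lags.**  No sub-sample interpolation; the per-axis lag
  quantization error is at most one sample, so recovered velocities
  satisfy `|1/CV − 1/CV*| ≤ (|cos φ*| + |sin φ*|)/(fs·d)`.  The
  smallest representable nonzero velocity is `d/(√2·d_SS) ≈ 4.95 cm/s`
  when both lags saturate, `d/d_SS = 7 cm/s` on a single axis — true
  lags beyond the search range clamp at its edge.

## Features

For each annotated interval (dummy = non-contraction, contraction) and
band, with `N` correlation intervals whose centers lie in the half-open
interval span:

* `P_V = 100·N_V/N`, `P_H = 100·N_H/N` — percentages of estimates with
  a nonzero velocity vector in the vertical/horizontal direction (the
  denominator counts all estimates, including `CV = 0` ones);
  `RP_VH = P_V/P_H`.
* `V̄_V`, `V̄_H` — mean CV by direction over nonzero estimates;
  `RV_VH = V̄_V/V̄_H`.  Per-sector analogues (`P_S, P_N, P_E, P_W`,
  `V̄_S, …`) split the same counts, so
  `P_S + P_N + P_E + P_W = P_V + P_H` identically.
* Ratios or means with empty denominators are flagged NaN and excluded
  pairwise downstream, never imputed.
* `SE_S2`, `SE_S3` — sample entropy (`m = 3`, `r = 0.15`) of the
  band-filtered S2/S3 segments cropped to the interval.  `r` is
  interpreted as a fraction of the segment's standard deviation (the
  convention of the SampEn literature; an absolute-`r` mode exists).
  Matching uses Chebyshev distance `≤ r`, self-matches excluded, both
  template lengths counted over the same start range; `SampEn =
  −ln(A/B)`.  No decimation is applied before the computation.

## Classification protocol

Preterm is the positive class.  Per-feature separability uses a
two-sample pooled-variance t-test.  Classification uses quadratic
discriminant analysis (equal priors, covariance regularization
`reg_param = 1e−6`) under stratified 10-fold cross-validation repeated
30 times with distinct fold shuffles; metrics are Se, Sp, CA (from
confusion totals pooled over folds) and AUC (from the continuous
posterior score), averaged over repetitions.  Class imbalance (e.g. 47
preterm vs 53 term intervals) is removed by SMOTE: synthetic minority
samples drawn uniformly on segments between a minority sample and one
of its k = 5 minority nearest neighbors, bringing the minority to the
majority count.  Two placements are first-class: `pre` balances the
whole set before cross-validation (the protocol this package chases),
`in_folds` balances training folds only, giving leakage-free estimates;
reports name the mode.  Repetition seeds derive from a master seed by
fixed offsets, making every report bit-reproducible.

## Synthetic data

`simulate_record` builds electrode potentials as delayed copies of a
burst waveform (Gaussian-windowed sinusoid by default, carrier 1.5 Hz
inside band B1) with delays `τ_i = p_i·u/CV*` from the plane-wave
geometry, plus optional white noise; bipolar channels are derived
exactly from the potentials, so the `S4 = S1 − S2 + S3` identity holds
by construction.  Two deliberate departures from the idealized model:

* **Amplitude gradient (default 10% per array span, both axes).**  A
  pure-delay plane wave travelling exactly along an array axis makes
  one bipolar pair identically zero — both of its electrodes lie on
  the same wavefront — so no lag estimator could measure that axis.
  Real tissue attenuates inhomogeneously; the small static gradient
  reproduces that and keeps all directions measurable while leaving
  correlation-peak locations essentially unchanged.
* **Burst width 0.5 s.**  The correlation envelope of a Gaussian burst
  decays as `exp(−m²/4σ²)`; long narrowband bursts leave the
  carrier-period aliases of the correlation maximum nearly degenerate.
  A 0.5-s burst (≈0.6 Hz bandwidth) separates the aliases while
  staying inside the analysis bands.

What the generator does *not* emulate: curved or dispersive wavefronts,
waveform change across electrodes beyond the static gain, physiological
background activity (maternal ECG, breathing), electrode artifacts, or
any anatomically realistic source.  Passing recovery tests therefore
demonstrates correctness of the estimator under its own model
assumptions, not performance on real recordings.

`simulate_feature_cohort` samples per-class Gaussian feature vectors
whose default means follow the reported direction of effects for dummy
intervals above 1 Hz — preterm: lower `P_V`, higher `P_H`, lower
`SE_S2` — with 47 preterm + 53 term members; it exists to exercise the
statistics/classification stage, not to imitate real feature
distributions.

## Problem sizes and verification scale

The verification suite runs at desk scale: 60-s single-wave records for
the recovery sweep (6 velocities × 10 angles, restricted to
combinations whose true per-axis lags fit the ±1 s search range),
80-sample windows × 1000 pairs for the lag-search oracle, series of
50–500 samples × 100 for the sample-entropy oracle, and 106-sample
cohorts for the classifier checks.  The permutation null for the
classifier re-shuffles labels on every repetition: a single fixed
permutation of clustered data retains chance imbalance that QDA can
genuinely exploit, so only the permutation average is expected to sit
at 50%.

## Known limitations

* Full-record analysis of the public term/preterm dataset requires a
  one-time download; the repository ships no recordings.
* Lag quantization at 20 Hz limits velocity resolution (e.g. between
  7/(14/20) = 10 and 7/(13/20) ≈ 10.8 cm/s there is no representable
  value); reported velocities inherit this granularity.
* The in-band power fraction of the fourth-order band-pass (applied
  bidirectionally) is ≈93% for the narrow bands — band edges are not
  brick walls, and neighboring activity leaks accordingly.
* With SMOTE applied before cross-validation (`pre` mode), synthetic
  minority samples derived from test-fold members appear in training
  folds; accuracies in that mode are optimistic by construction.  Use
  `in_folds` for honest generalization estimates.
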