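# ehgprop

Conduction-velocity and propagation-direction analysis of uterine
electrohysterogram (EHG) surface records, for researchers working on
non-invasive preterm-birth prediction.

Four bipolar signals from a square abdominal electrode grid (side
d = 7 cm) see a planar EHG wave as time-shifted copies of one another.
Short-time cross-correlation between the upper/lower pair (S1, S3) and
the left/right pair (S2, S4) yields the vertical and horizontal
similarity shifts s_V, s_H at every 0.5-s step; transitional times
t = −s/f_S give the conduction-velocity amplitude and incidence angle

    CV = d / √(t_V² + t_H²),      φ = atan2(t_H, t_V),

with φ measured from the vertical axis and mapped to the south / east /
north / west sectors.  Estimates with both shifts zero (no propagation)
or CV > 30 cm/s (outliers) are zeroed.  Public datasets record only
three bipolar signals; the fourth follows exactly from the electrode
potentials, S4 = S1 − S2 + S3.

Per annotated interval (dummy or contraction) and frequency band
(B0′ 0.3–1.0, Bb 0.3–4.0, B1 1.0–2.2, B2 2.2–3.5, B3 3.5–5.0 Hz) the
velocity track is aggregated into the directional percentages P_V, P_H,
mean velocities V̄_V, V̄_H, their ratios RP_VH and RV_VH, per-sector
statistics, and the sample entropies SE_S2, SE_S3 (m = 3, r = 0.15·SD).
A SMOTE-balanced QDA classifier under stratified 10-fold
cross-validation with 30 repetitions separates preterm from term
records on these features.

A built-in planar-wave simulator with known ground truth (velocity,
angle, waveform, noise) makes every stage verifiable without any data
download.  See `docs/methods.md` for the model, parameter meanings and
numerical choices.

## Worked example

Simulate a record carrying planar waves with CV* = 10 cm/s and
φ* = 30° (south sector), then track it in band B1:

```sh
ehg simulate --cv 10 --phi 30 --n-waves 2 --duration 80 --seed 4 --out rec
ehg velocity --record rec/synth_cv10_phi30.hea --band B1 --out track.csv
```

The rows of `track.csv` covering the first wave (onset 20 s) read:

```
 k  center_s  s_V  s_H  t_V  t_H   CV_cm_s   phi_deg direction sector
33      19.0  -12   -7  0.6 0.35 10.077421 30.256437  vertical  south
34      19.5  -12   -7  0.6 0.35 10.077421 30.256437  vertical  south
35      20.0  -12   -7  0.6 0.35 10.077421 30.256437  vertical  south
```

The shifts of −12 and −7 samples at 20 Hz give transitional times of
0.60 s and 0.35 s, hence CV = 7/√(0.6² + 0.35²) ≈ 10.08 cm/s and
φ ≈ 30.3° — the true velocity and angle up to the one-sample lag
quantization (there is no sub-sample interpolation, so exactly 10 cm/s
at 30° is not representable).  Sector `south` matches the simulated
direction.  Note that negative vertical shift means downward travel —
the sign convention is anchored to the wave geometry, not to the raw
correlation formula.

`ehg features` turns tracked records plus their interval annotations
into the per-interval feature table, `ehg classify` runs the
QDA protocol over feature subsets, and `ehg run-all` chains
simulate → preprocess → velocity → features → classify into a
manifest-stamped artifact directory.

For real data: records in WFDB format (.hea/.dat, format 16) are read
directly; interval annotations use paired begin/end marks with a
configurable symbol table (see `ehgprop.io`).

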