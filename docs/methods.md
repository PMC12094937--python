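# Methods

## The freeze index

Freezing of gait (FOG) in Parkinson's disease manifests as trembling in
place: during an episode the dominant energy of a leg- or trunk-worn
accelerometer shifts from the stepping ("locomotion") band into a higher
"freeze" band. The freeze index (FI) tracks this shift. For a proxy signal
x(t) and a sliding window of length T centered at t,

    FI(t) = ln( 100 * ∫_[f_t, 8] PSD(f) df / ∫_[0.5, f_t] PSD(f) df ),

where f_t is the locomotion–freeze threshold frequency (default 3 Hz),
PSD is the spectral density of the windowed signal, and ln(100·) is the
conventional logarithmic normalization that maps a band-power ratio of
0.01 to zero. The ratio is deliberately *not* squared: after the
logarithm, squaring is only a factor of 2 and carries no information.

## The standardized multitaper estimator

Per window (`estimate_fi_multitaper`):

1. **Linear detrend** — remove the least-squares line so slow drifts do
   not leak into the locomotion band.
2. **Slepian (DPSS) multitapering** — multiply the window by each of L
   orthonormal DPSS tapers with standardized half-bandwidth B and sum the
   squared FFT magnitudes. Multitapering trades a controlled amount of
   spectral resolution (±B/T Hz) for a large variance reduction relative
   to a single periodogram.
3. **Zero-padding** — FFT length is the smallest power of two ≥ 4× the
   window sample count. Padding refines the integration grid so the band
   edges are resolved consistently at every sampling frequency; it does
   not add information.
4. **Trapezoidal band integration** over the grid nodes inside each
   closed band, then `FI = ln(100 · P_freeze / P_loco)`.
5. **Optional moving average** of the FI series (`maf_width` seconds,
   default 0 = off; the kernel is rounded up to an odd sample count and
   shrinks symmetrically at the series edges).

All constant scalings (FFT normalization, 1/L averaging, the one-sided
doubling) are omitted — they cancel in the ratio.

Defaults: `window` T = 5.0 s, `n_tapers` L = 4, `half_bandwidth` B = 2.5,
`f_threshold` = 3 Hz, `step` = 0.1 s. T/L/B balance smoothness against
responsiveness; at most ⌊2B⌋−1 = 4 well-concentrated tapers exist for
B = 2.5, and the constraint L ≤ ⌊2B⌋−1 is enforced. The 0.1 s hop matches
the finest granularity used by any historical definition. Seconds convert
to samples by round-half-up, ⌊z + 0.5⌋, everywhere; a nominal hop below
one sample (Cockx's 1/256 s step at 64 Hz) clamps to one sample.

Windows are fully interior: FI values exist for centers in
[t0 + T/2, t_end − T/2]; no partial-window extrapolation. A window with
zero or non-finite band-power ratio yields NaN (with a logged count); a
series that is entirely NaN is an error.

## Legacy definitions

Four historical FI definitions are reproduced as `MethodSpec` instances:

| name    | T [s] | step [s] | loco [Hz] | freeze [Hz] | preprocessing  | ratio²| ln(100·) |
|---------|-------|----------|-----------|-------------|----------------|-------|----------|
| moore   | 6.0   | 0.5      | 0.5–3     | 3–8         | none           | yes   | yes      |
| bachlin | 4.0   | 0.5      | 0.5–3     | 3–8         | mean subtract  | no    | no       |
| zach    | 2.0   | 0.1      | 0.5–3     | 3–8         | none           | yes   | yes      |
| cockx   | 3.0   | 1/256    | 0.5–3     | 3.5–8       | Hann taper     | yes   | yes      |

All use the raw squared-magnitude FFT periodogram (no detrending, no
multitapering — faithfully reproducing the original omissions). Design
choices that the historical descriptions left open, resolved here:

- **Moore's hop** was never stated; 0.5 s is adopted from its direct
  descendant (Bachlin). Similarity analysis resamples all series, so this
  only affects series density.
- **Squaring/normalization flags** were never stated as flags; they are
  derived by inverting each definition's published flat-spectrum
  reference value: ln(400) ⇒ squared + normalized (Moore, Zach), a plain
  2.00 ⇒ neither (Bachlin), ln(324) ⇒ squared + normalized with a
  4.5-Hz-wide freeze band (Cockx).
- **Cockx's band gap**: the loco band tops out at 3.0 Hz while the freeze
  band starts at 3.5 Hz; the 3–3.5 Hz gap is preserved because the
  ln(324) reference value is only consistent with a 2.5-Hz-wide loco
  band.
- The **Hann window** is the symmetric variant, which keeps every
  estimator exactly invariant under time reversal of a window.
- Whether Moore/Zach windows were detrended is unknown; they are
  implemented literally with no preprocessing.

`theoretical_white_noise_fi` evaluates each definition's closed-form
value on an ideal flat spectrum (the ratio of band widths, squared and/or
log-normalized as the definition prescribes): ln(200) ≈ 5.298 for the
standard definition, ln(400) ≈ 5.991 for Moore/Zach, 2.000 for Bachlin,
ln(324) ≈ 5.781 for Cockx.

## White-noise benchmark

Gaussian white noise has a flat spectrum, so an ideal estimator would
return the closed-form value at all times. `run_white_noise_benchmark`
generates M = 10 standard-normal signals per sampling frequency
(64, 100, 256 Hz — the rates used historically), feeds the *identical*
realizations to every method, and reports the mean ± sd over trials of
the per-trial FI standard deviation and of the per-trial RMSE from that
method's own closed-form value. Statistics are computed per trial and
then averaged, with NaN windows excluded. The multitaper moving average
stays off in the benchmark so the estimator's intrinsic variance is
measured, not the smoother.

Trial length is 300 s — ≥ 2950 FI samples at the default hop, enough for
a stable per-trial standard deviation while the full 5-method × 3-rate ×
10-trial table completes in about a minute. Per-trial seeds derive from
one base seed by a documented counter scheme
(`seed·100003 + fs·131 + trial`, mod 2³¹) and are logged in the result
table.

`sweep_hyperparameters` recomputes raw (non-standardized) multitaper FI
series while varying one of T, L, B, f_t; combinations violating
L ≤ ⌊2B⌋−1 are skipped with a warning. On signals with narrowband freeze
content the threshold f_t moves the FI far more than T, L, or B — the
band definition, not the spectral machinery, is the sensitive choice.

## Similarity analysis

Different definitions hop at different rates and live on different
scales, so before comparison all series are (1) restricted to their
common time interval (different window widths make series start at
different centers; non-overlapping tails are not comparable),
(2) linearly interpolated to a common length — by default the longest
input series, which discards no resolution — and (3) standardized to
zero mean and unit *population* (divide-by-n) standard deviation.

Pairs are scored by mean absolute distance (MAD — "distance" because
neither series is ground truth), Pearson ρ, and R². R² is asymmetric;
within a pair the series earlier in the registered order (multitaper,
moore, bachlin, zach, cockx) is the reference.

The leave-one-out meta-comparison asks whether one definition is an
outlier: its pair scores (set A) are compared with all remaining pair
scores (set B) via a range-based intersection-over-union — the overlap
of the intervals [min, max] spanned by each set divided by their hull.
1 means the test definition's scores span the same range as the rest;
0 means no overlap. A degenerate hull (all scores identical) is defined
as perfect overlap (IOU 1). With multiple recordings, IOUs are computed
per recording rather than pooled.

## Synthetic data

`generate_white_noise` produces the flat-spectrum benchmark signal
(standard-normal i.i.d. samples, seeded). `generate_gait_with_fog`
concatenates labeled segments: *walk* is a cadence fundamental plus its
2nd and 3rd harmonics (defaults 0.9 / 1.8 / 2.7 Hz, amplitudes 1 : 1/2 :
1/3) plus white noise; *freeze* is a single tremble sinusoid (default
5 Hz) plus noise; *stand* is noise only. The default cadence of 0.9 Hz —
a realistic stride rate — keeps all walking harmonics strictly below the
3 Hz band edge so fixtures exercise the band contrast rather than the
edge ambiguity. Default noise sd is 0.1 of the unit oscillation
amplitude.

These fixtures emulate exactly the spectral contrast the FI assumes.
They are **not** biomechanically realistic: no turns, voluntary stops,
posture changes, gravity re-orientation, impact transients, or sensor
artifacts — the known confounders of the FI in real recordings. Tests
passing on them demonstrate the estimation machinery, not clinical
validity.

`write_daphnet_fixture` / `make_daphnet_fixture` emit the synthetic
signals in the Daphnet plain-text dialect (11 integer columns at 64 Hz,
accelerations in mg, annotation 0/1/2) so the file-based pipeline and
CLI run end to end without any download. mg values round by the same
⌊z + 0.5⌋ convention.

## Scope and limitations

- FI estimation only: FOG/no-FOG classification thresholds, their
  validation, and clinical interpretation are out of scope. Annotation-0
  samples ("outside the experiment") are retained in extracted proxies;
  masking is the consumer's decision.
- Absolute PSD values are unanchored (one-sided, unscaled); only band
  ratios are meaningful.
- White-noise benchmark statistics here run a few percent *below* some
  historically reported variabilities; the benchmark bounds accept
  smaller variance, and all method rankings are preserved.
- The moving-average width has no principled default; it is off unless
  requested.
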