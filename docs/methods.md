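# Methods

## Signal model and pipeline order

Audio is mono, nominally 16 kHz, amplitudes in [−1, 1] (integer PCM is
divided by full scale on read, so the detection threshold is scale-free).
All short-time analysis uses N = 512-sample frames with 50 % overlap under
a periodic Hamming window; trailing partial frames are dropped rather than
zero-padded to avoid spectral bias in the last frame. The pipeline order is
denoise → detect → extract → classify; whether spectral features are taken
before or after spectral subtraction is a config switch (default: after).

### Denoising

A zero-phase order-5 Butterworth band-pass (default 300–7500 Hz,
`denoise.low_hz`/`high_hz`) removes mains hum and ventilation rumble while
keeping a margin below the 8 kHz Nyquist. The stationary background is then
estimated per recording file — barn noise drifts across hours but is
near-stationary within one ~55 s file — as the mean magnitude spectrum of
the lowest-energy `denoise.quantile` (default 0.1) of frames, and removed
per frame as

    |X|' = max(|X| − α·|N|, β·|X|),   α = subtraction_factor (1.0),
                                      β = spectral_floor (0.02),

phase preserved. The multiplicative floor guarantees non-negative
magnitudes and bounds the worst-case musical-noise artefacts. Whole-clip
denoising reconstructs by Hann-weighted overlap-add with the exact synthesis
weights divided out, so output length equals input length sample for sample.

### Event selection

The detection statistic is the per-frame RMS (optionally RMS², config
`detect.use_energy`), smoothed by a 3-frame centred moving average and
normalised by its per-file maximum. Maximal runs at or above
`detect.threshold` (default 0.35) become events; runs separated by gaps
≤ 30 ms merge, and events shorter than 30 ms are discarded — short enough
to keep sub-100 ms squawk notes, long enough to kill single-frame clicks.
Event edges are placed half a frame outside the first/last supra-threshold
frame centres. Detected↔labelled agreement uses the overlap factor
(interval Jaccard) with greedy best-overlap one-to-one assignment;
threshold tuning maximises the mean best-match overlap over a grid, ties
going to the larger threshold (fewer false alarms).

## Feature extraction

Two frame grids coexist deliberately. Spectral features (ZCR, spectral
spread/energy/centroid) are computed on the pipeline's 512/256 Hamming
frames and averaged over the event. Pitch and formant *tracks* use short
contiguous 256-sample frames without overlap, so that "consecutive periods"
in the jitter/shimmer definitions are genuinely disjoint stretches of
signal; with 50 % overlap, half of every difference would be shared signal
and perturbation would be systematically underestimated. Events shorter
than one frame are zero-padded to a single frame; an event whose nine
features are all missing is dropped with a log entry, and individual
missing features are NaN (imputed only at classification time with
training-pool medians).

* **f0** — per-frame autocorrelation via FFT, 8× oversampled in lag and
  unbiased by N/(N−lag). Both corrections matter: with integer-lag sampling
  of a sharp ACF peak, whichever *multiple* of a non-integer true period
  falls nearest an integer lag wins the argmax. The chosen lag is the first
  local peak reaching 97 % of the global maximum (resolving period
  doubling toward the fundamental), refined by parabolic interpolation.
  Voicing requires a normalised peak ≥ 0.35; the search band is 200–4000 Hz
  (hen calls concentrate below ~2 kHz but alarm fundamentals reach higher).
* **F1–F3** — order-12 linear prediction (Levinson–Durbin on the
  pre-emphasised, Hamming-windowed frame); resonances are upper-half-plane
  roots with bandwidth < 700 Hz, sorted ascending. The per-formant
  *amplitude* is the frame's spectral power integrated under a 300 Hz-σ
  Gaussian centred on the **track-median** formant frequency: evaluating
  the all-pole envelope at each frame's own pole is far too sensitive to
  pole-radius noise, and re-centring per frame leaks frequency jitter into
  the amplitude track.
* **jitter/shimmer** — mean |first difference| over mean value, over
  present frames. Shimmer is computed on the central 50–100 % of the track
  (outer 25 % per side trimmed when ≥ 2 frames remain): the deterministic
  onset/offset ramp of a call is not cycle-to-cycle amplitude perturbation,
  and leaving it in adds ≈ +0.25 of spurious shimmer on ramped calls.
  The feature table lists shimmer for F1 and F3 only (no F2); that layout
  is kept as-is.
* **spectral energy** — log10 of the sum of squared max-normalised bin
  energies; bounded above by log10(#bins) and exactly 0 for a single
  occupied bin.

All nine features are invariant to global gain by construction (checked at
±20 dB).

## Classification

One binary soft-margin SVM per class (class vs rest); prediction is the
argmax of decision values with ties broken by the fixed class order alarm,
gakel, squawk, others. Features are median-imputed and standardised to
zero mean/unit variance with statistics frozen from the training portion
only — γ = 0.2 is meaningless across raw scales (Hz next to proportions).
Defaults: polynomial kernel (γ = 0.2, coef0 = 1, degree = 3), C = 1,
solver capped at 10,000 iterations at 1e-4 tolerance. Cross-validation is
stratified (a rare class like gakel must appear in every fold), seeded, and
reports per-fold confusion matrices, their pooled sum, and per-class
mean ± SD of sensitivity/precision; the macro figure is the unweighted mean
over the four classes. Forward feature selection and grid search both
optimise the mean CV macro criterion; selection ties prefer the smaller
canonical feature index, grid ties the smaller C then lower degree. The
quadratic-programming solver behind each binary machine is scikit-learn's
`SVC`; the one-vs-all scheme, scaling, imputation, CV, selection and search
logic, and the JSON model serialisation (support vectors + explicit kernel
formulas, so a reloaded model predicts identically) are implemented here.

## Thermal comfort

THI defaults to the laying-hen parameterisation
0.8·T + (RH/100)·(T − 14.4) + 46.4 with every coefficient configurable; the
coefficient set in force is embedded in output metadata. The published
integer zone bands leave gaps (75–76, the endpoint 81), so zones are closed
half-open — comfort < 70 ≤ alert < 76 ≤ danger ≤ 81 < emergency — making
the mapping total and monotone. Calls are counted per 5-minute half-open
window (boundary events go to the later window); counts are min–max mapped
per call type onto 10 equal-width levels (constant series → level 1).
Correlation is Pearson r with a two-tailed p from the t distribution on
n − 2 df, flagged at the 0.01 level; no multiple-testing correction is
applied, which the output metadata notes.

## Synthetic data

The generator emulates what the pipeline must cope with, not hen acoustics
per se. Each call is additive-harmonic: a source at a drawn f0 (strong
fundamental, mild 1/h^0.3 tilt) weighted by Gaussian bumps at three
formant frequencies, shaped by a gradual (25 % raised-cosine) or abrupt
(1 ms) onset envelope. Frequency and amplitude perturbations are
piecewise-constant per 256-sample block — the pitch/formant analysis frame
— with alternating signs and magnitudes drawn around target/2, so the
realised frame-to-frame jitter/shimmer of even a 3-frame squawk sits close
to its target; independent draws would leave single short calls far from
target purely by chance. Class parameter ranges live in
`src/henvox/data/call_classes.yaml`; f0 bands overlap between neighbouring
classes so that separation rests on the joint feature vector. Background is
pink noise plus 50/100 Hz hum; calls are placed non-overlapping at a
per-call SNR (default 15 dB), and a configurable fraction of deliberately
overlapping pairs is labelled rating 1 and excluded from training, matching
how overlapped calls are handled in practice.

What the corpus does **not** emulate: reverberation, flock chorus overlap
beyond the rating-1 pairs, non-stationary machinery noise, cage rattle, or
genuinely hen-like spectro-temporal detail. Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under calibrated
noise, not field performance on real barns.

The thermal generator draws THI uniformly over [60, 90] (all four zones)
and per-window counts from Poisson(5·exp(b·z)) in the standardised THI z,
with default couplings b = −0.2 (alarm), 0 (gakel), +0.3 (squawk), +0.1
(others). A delta-method approximation r ≈ b·λ̄/√(λ̄ + b²λ̄²) puts the
expected correlations near −0.41 and +0.56, i.e. the magnitude regime of
interest; only the signs are treated as the recoverable property.

## Problem sizes and numerical choices

Tests and the acceptance script use 400-call corpora (100 per class) for
classification and 200 thermal windows; at these sizes the full pipeline
runs in seconds while fold metrics are stable to a few percent. Degenerate
inputs resolve as: all-zero envelope → no events (no division by the
maximum); zero-variance series → flagged undefined correlation, never 0;
TP+FN = 0 → flagged undefined metric; sub-frame events → single padded
frame; < 2 present track values → missing feature. Percentages round half
up to one decimal (`decimal`-based, not banker's rounding). Determinism:
every stochastic component (synthesis, folds, SVC) is seeded, and reports
contain no wall-clock state, so identical seed + config reproduce outputs
byte for byte.

## Known limitations

Single-microphone, single-flock design; no online/streaming detection; no
source separation for overlapped calls (they are excluded by rating);
jitter/shimmer are frame-level approximations of period-level perturbation
and depend on the 256-sample track frame; the THI formula is one of several
in use and should be chosen to match the husbandry context.
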