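# henvox

Acoustic monitoring of laying-hen welfare: detect hen vocalisations in
continuous barn audio, classify them as **alarm / gakel / squawk / others**,
and relate call rates to the **temperature–humidity index (THI)** to flag
heat stress.

Hens vocalise differently under stress: squawks (distress cries, < 0.1 s,
wide-band, abrupt onset) become more frequent in hot conditions, while
alarm calls (high-pitched, < 0.2 s, harmonic) become rarer; gakel calls
(soft, low-frequency, clearly harmonic) indicate frustration. Because no
recordings of this kind are openly available, the package ships a seeded
source-filter call synthesiser, so every stage is testable end to end
without any field data.

## Method

The pipeline follows standard bioacoustic practice:

1. **Pre-processing** — frames of N = 512 samples with 50 % overlap and a
   Hamming window at 16 kHz; zero-phase band-pass (300–7500 Hz) plus
   Boll-style spectral subtraction against a per-file noise profile
   estimated from the quietest 10 % of frames.
2. **Event selection** — the smoothed frame-RMS envelope, normalised per
   file, is thresholded at 0.35 of its maximum; supra-threshold runs become
   events `[start, end)`. Agreement with labels is scored by the *overlap
   factor* (interval intersection-over-union), and the threshold can be
   tuned by maximising it on labelled clips.
3. **Features** — nine source-filter and spectral features per event, in
   fixed order: jitter(f0), jitter(F1), jitter(F2), shimmer(F1),
   shimmer(F3), zero-crossing rate, spectral spread, normalised spectral
   energy `E = log10 Σ (Xₙ/X_max)²`, and spectral centroid. Jitter/shimmer
   are the mean absolute frame-to-frame difference divided by the mean
   (`Σ|xᵢ₊₁−xᵢ|/(k·x̄)`); f0 comes from an oversampled autocorrelation
   tracker and F1–F3 from order-12 linear prediction.
4. **Classification** — one-vs-all soft-margin SVMs over standardised
   features; default kernel `K(x,y) = (0.2·xᵀy + 1)³` with C = 1, evaluated
   by stratified 5-fold cross-validation (sensitivity = TP/(TP+FN),
   precision = TP/(TP+FP)); greedy forward feature selection and an
   exhaustive hyperparameter grid search are included.
5. **Thermal comfort** — THI = 0.8·T + (RH/100)·(T − 14.4) + 46.4 (zones:
   comfort < 70 ≤ alert < 76 ≤ danger ≤ 81 < emergency); calls are counted
   per 5-minute window, normalised onto levels 1–10, and correlated with
   THI (Pearson r, two-tailed t-test on n − 2 df).

## Worked example

```python
from henvox import build_corpus
from henvox.config import PipelineConfig
from henvox.pipeline import corpus_features, train_config
from henvox.classify import cross_validate

cfg = PipelineConfig(); cfg.seed = 7
corpus = build_corpus(n_per_class=40, snr_db=15.0, seed=7)
X, y, stats = corpus_features(corpus.clips, corpus.truth_events, cfg)
mm = cross_validate(X, y, train_config(cfg)).metric_mean_sd()
print(stats)
print(mm["sensitivity"]["macro"], mm["precision"]["macro"])
```

prints

```
{'n_labels': 160, 'n_detected': 164, 'n_matched': 160, 'n_featured': 160}
95.0 95.3125
```

i.e. all 160 synthetic calls were detected and matched to their labels
(with 4 false alarms), and the classifier recognised the four call types
with ~95 % macro sensitivity and precision under 5-fold cross-validation.
The scripts in `examples/` walk through each capability (corpus synthesis,
detection + feature extraction, classification + feature selection, THI
correlation) and print annotated output; a thin `henvox` command-line
interface exposes the same stages (`henvox synth`, `detect`, `extract`,
`train`, `cv`, `select-features`, `evaluate`, `comfort`, `run`).

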