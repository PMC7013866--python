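# Acoustic parameter ranges for the four synthetic hen-call classes.
#
# The classes mirror the qualitative contrasts of real hen vocalisations:
#  - gakel:  soft, brief (<0.2 s) notes with clear harmonic structure and
#            emphasis below 2 kHz; low cycle-to-cycle perturbation.
#  - alarm:  high-pitched, short (<0.2 s), distinctly harmonic, clean.
#  - squawk: very short (<0.1 s) wide-band notes with abrupt onset/offset
#            and strong frequency/amplitude perturbation (distress-like).
#  - others: residual class; broadband cluck-like notes of variable length.
#
# Ranges are [low, high] for uniform draws.  f0 bands deliberately overlap
# between neighbouring classes so separation rests on the joint feature
# vector (perturbation, spectral shape, onset) rather than pitch alone.
# jitter / shimmer are the *measured* frame-to-frame targets the generator
# aims for; the synthesis engine compensates internally for frame averaging.

alarm:
  duration_s: [0.08, 0.18]
  f0_hz: [1200.0, 1800.0]
  f0_jitter: [0.005, 0.02]
  n_harmonics: 4
  formant_freqs: [1500.0, 3200.0, 4800.0]
  amplitude_shimmer: [0.02, 0.06]
  onset_style: gradual

gakel:
  duration_s: [0.08, 0.18]
  f0_hz: [350.0, 650.0]
  f0_jitter: [0.005, 0.02]
  n_harmonics: 10
  formant_freqs: [700.0, 1900.0, 3300.0]
  amplitude_shimmer: [0.03, 0.08]
  onset_style: gradual

squawk:
  duration_s: [0.05, 0.095]
  f0_hz: [600.0, 1100.0]
  f0_jitter: [0.08, 0.15]
  n_harmonics: 12
  formant_freqs: [1200.0, 2600.0, 4200.0]
  amplitude_shimmer: [0.12, 0.25]
  onset_style: abrupt

others:
  duration_s: [0.10, 0.30]
  f0_hz: [300.0, 550.0]
  f0_jitter: [0.03, 0.07]
  n_harmonics: 7
  formant_freqs: [900.0, 2200.0, 3600.0]
  amplitude_shimmer: [0.06, 0.12]
  onset_style: gradual
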