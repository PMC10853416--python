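# eegfiction

EEG band-power analysis for text-type reading experiments: does the brain
respond differently to original fiction, imitative fanfiction, and
deliberately badly written "badfiction"?

`eegfiction` is a tested, reusable implementation of the spectral pipeline
such studies use, aimed at cognitive-neuroscience and digital-humanities
researchers who want to run, audit, or extend this kind of analysis without
starting from raw EEGLAB scripts:

* **Preprocessing** — zero-phase IIR band-limiting to 0.5–40 Hz, automated
  rejection of erroneous channels, and ICA-based removal of eye-blink and
  muscle artifacts with a transparent, probability-thresholded component
  scorer.
* **Spectral features** — per-stimulus power spectral density from 1-s
  Hamming windows stepped every 0.5 s (50 % overlap), absolute band powers
  `P_b`, relative band powers `R_b = Σ_{f∈b} P(f) / Σ_f P(f)` for the five
  QEEG bands (δ, θ, α, β, γ), and the brain rate
  `f_BR = Σ_b center(b) · R_b`.
* **Group statistics** — a one-way *permutation* ANOVA across the whole
  channel × frequency grid (Bonferroni-corrected) for text-type effects on
  absolute PSD, and a 31 × 6 × 5 cascade of two-group tests on the relative
  measures: Levene + Shapiro–Wilk decide between Student's *t*, Welch's
  *t*, and Mann–Whitney *U*; Benjamini–Hochberg FDR controls the family;
  Cohen's *d* quantifies each effect.
* **A from-scratch Kohonen self-organizing map** (6 × 6 hexagonal grid,
  10,000 iterations, bubble neighborhood) that clusters stimulus-level
  spectral features and predicts the text type being read, with a
  participant-level 70/30 holdout so no reader's data straddles the split.
* **A synthetic-EEG generator** that reproduces the study design — 40
  participants, 15 trials of [4 originals, 1 fanfiction, 4 originals,
  1 badfiction] at 500 Hz on a 32-channel 10/10 montage — with injectable,
  known-truth condition and group effects, so every stage has a
  parameter-recovery test bed and nothing requires a data download.

## Worked example

Simulate a ten-participant experiment in which badfiction halves β and γ
oscillator power and fanfiction quadruples θ power, then run the full
pipeline:

```sh
eegfiction run-all --config demo.json
eegfiction report --out-dir demo_out
```

with `demo.json` holding a reduced design (10 participants, 3 trials,
8 channels, 4–6 s stimuli, the two badfiction effects at magnitude 0.5 and
the fanfiction θ effect at 4.0). The report printed:

```
counts: {'participants': 10, 'stimuli': 300, 'feature_rows': 1800,
         'windows': 15384, 'cascade_tests': 180,
         'som_train_rows': 210, 'som_test_rows': 90}

text-type ANOVA: 164/240 significant cells
  Cz: 4-8, 15-39 Hz
  Oz: 4-8, 15-37, 39-40 Hz
  ...

group cascade: 0/180 significant after FDR

SOM confusion matrix (rows true / columns predicted):
        badfiction  fanfiction  original
badfiction       9           0         0
fanfiction       0           9         0
original         0           0        72
F1: badfiction 1.000, fanfiction 1.000, original 1.000; accuracy 1.000
```

Reading this: the permutation ANOVA localizes the injected effects — θ bins
(4–8 Hz) where fanfiction differs and β/γ bins (15–40 Hz) where badfiction
differs — while δ and α stay clean; no group effects were injected, so the
cascade correctly finds nothing after FDR; and the SOM, trained on 210
stimulus rows from seven participants, classifies all 90 held-out rows from
the other three. The frontal channel is absent from the ANOVA listing
because the automated channel rejection dropped it (blink-loaded), which
the run log records.

The same stages are available as a library (`eegfiction.simulate`,
`.preprocess`, `.spectral`, `.stats`, `.som`) for use in notebooks and
scripts.

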