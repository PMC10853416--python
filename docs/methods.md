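# Methods

This note documents the models, numerical choices, and limitations behind
`eegfiction`. It is written for a reader who wants to know exactly what the
pipeline computes and what passing its tests does and does not establish.

## Signal model of the synthetic generator

Each participant's recording is a sum of

1. **Band oscillators.** One narrowband Gaussian process per frequency band
   (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–40 Hz), synthesized in the
   frequency domain — complex Gaussian coefficients on exactly the DFT bins
   inside the band, inverse-transformed and scaled to a target variance —
   so band confinement is exact by construction. A pure-tone mode (a
   sinusoid at the band center with random phase) exists for oracle tests
   where closed-form spectra are needed. Baseline per-band powers are
   36/25/64/9/2.25 µV² (an alpha-dominant, eyes-open adult profile), flat
   across channels.
2. **1/f background.** Pink noise shaped as `f^(-β/2)` in amplitude
   (β = 1 by default, flattened below 0.5 Hz), RMS 4 µV.
3. **Sensor noise.** White, 2 µV RMS.
4. **Artifacts.** Poisson-scheduled blink transients (Gaussian bumps of
   ~0.4 s, 80 µV, frontally weighted: Fp1/Fp2 > F7/F8 > F3/F4/Fz) and
   muscle bursts (0.3 s Hann-windowed 20–45 Hz noise, 15 µV, temporally
   weighted: T7/T8 > FT9/FT10 > TP9/TP10).

**Effects** are the generator's ground truth. `absolute_scale` multiplies a
band's oscillator power by a factor wherever the effect applies (a text
type or a participant-group level, optionally a channel subset);
`relative_shift` adds a signed amount to the band's power *fraction* and
rescales the other bands so total power is conserved. `truth_table()`
exposes the resulting expected absolute and relative powers before noise,
and is the recovery target for all parameter-recovery tests.

**Design defaults** are the emulated study's conditions: 40 participants,
15 trials of the 10-stimulus pattern [4 originals, fanfiction, 4 originals,
badfiction] (150 stimuli: 120/15/15), 500 Hz, the 32-channel 10/10 montage,
and group sizes frequent/non-frequent 10/10, buffs/rookies 12/14,
fantasy/non-fantasy 26/14, fans/non-fans 17/23, positive/negative 9/8
(remainders in a rest category that two-group analysis excludes). Stimulus
reading times are drawn uniformly from 8–15 s — a plausible silent-reading
time for a ~40-word passage; no per-stimulus timing distribution is
published, so this is a configurable assumption. Each participant's draws
come from an independent stream seeded by (master seed, participant index),
so enlarging a design never perturbs existing participants, and identical
(spec, seed) yields bit-identical recordings.

**What the generator does not emulate:** volume conduction and realistic
scalp topography (band powers are channel-flat up to artifacts), evoked
transients/ERPs, non-stationarity within a stimulus, inter-participant
amplitude variability, and line noise. Passing recovery tests therefore
shows the *machinery* extracts injected band-power structure correctly; it
does not validate any claim about real reading EEG.

## Preprocessing

* **Band-limiting.** Zero-phase (forward–backward) elliptic IIR filters:
  high-pass cutoff 0.5 Hz, effective order 6; low-pass cutoff 40 Hz,
  effective order 12 (design orders are half, since `sosfiltfilt` doubles
  them). Elliptic designs were chosen because the binding contract is the
  narrow transition band — signal essentially gone below 0.3 Hz and above
  41 Hz at these orders — which a Butterworth of the same order cannot
  deliver (an order-12 Butterworth at 40 Hz attenuates 45 Hz by only
  ~14 dB). With 0.05 dB passband ripple and 25 dB stopband per pass, the
  combined response is ≥ 40 dB down at DC and at 45 Hz while 10 Hz passes
  within 0.5 %.
* **Channel rejection.** The study rejected channels by manual inspection,
  which is not reproducible; the pipeline instead z-scores each channel's
  variance against the channel population using median/MAD (robust to the
  outliers being tested for) and drops |z| > 5 by default. Dropped channels
  are logged, never interpolated.
* **ICA.** FastICA (whitened, unit-variance sources, fixed seed) stands
  behind `decompose_ica`; any decomposition passing the separability oracle
  (correlation ≥ 0.95 on constructed super-Gaussian mixtures) would do.
  Requires ≥ 20·k² samples for k components; rank-deficient data reduces k
  with a warning.
* **Component scoring.** In place of a trained component classifier (out of
  scope), components are scored by transparent features: eye score ∝
  (Fp1/Fp2/F7/F8 squared-loading share) × (sub-4 Hz power fraction), muscle
  score ∝ (T7/T8/FT9/FT10 share) × (>20 Hz fraction), brain score ∝ 4–20 Hz
  fraction on non-peripheral topography, plus a small constant floor for
  "other"; normalized per component. Spectral fractions are computed within
  0–45 Hz so broadband sensor noise does not masquerade as muscle.
  Components whose eye or muscle probability reaches the threshold
  (0.85 default; 0.80/0.75 available for noisier data, always an explicit
  config choice, never auto-selected) are zeroed and the data
  back-projected. Removal is idempotent for a fixed decomposition because
  the flagged subspace is projected out exactly.
* **Windowing.** Stimulus intervals are cut into 1-s windows every 0.5 s
  (Hamming-tapered downstream); a window must lie fully inside the
  stimulus, so an interval of duration `d` yields
  `floor((d − 1)/0.5) + 1` windows (0 if `d < 1`).

## Spectral features

Per window: Hamming-tapered periodogram with Welch density normalization
(`1 / (fs · Σ taper²)`, off-DC bins doubled), averaged over a stimulus's
windows, restricted to the exact 1-Hz grid 1–40 Hz that a 1-s window at
500 Hz provides. The 0 Hz bin is excluded (high-pass region).

Absolute band power `P_b` is the **mean** per-bin power in the band (the
convention for absolute comparisons); relative power `R_b` uses **summed**
bin power normalized by total summed power, which guarantees `Σ R_b = 1`
exactly despite unequal band widths. The brain rate is the relative-power
weighted mean of band centers, `f_BR = Σ_b center(b)·R_b` — the published
concept is cited without a printed formula, so this weighted-mean reading
is documented as the package's interpretation, with centers derived from
the (configurable) band edges; under the defaults `f_BR` always lies in
[2.25, 35] Hz. Absolute-level aggregation averages within participant
before averaging across participants, so unequal stimulus counts do not
bias condition means; relative-level analysis deliberately keeps
stimulus-level rows (see below).

## Statistics

* **Grid ANOVA.** Observation unit: per-(participant, condition) mean PSD
  at each (channel, frequency-bin) cell. The F statistic is compared
  against labels permuted uniformly across all observations (a
  within-participant permutation mode is a possible refinement; full
  permutation is the default because the observation rows are
  participant-condition summaries). p = (1 + #{F* ≥ F}) / (1 + n_perm);
  one shared permutation set serves all cells. Bonferroni uses the *global*
  family of all tested cells — the stricter reading. Note the resolution
  constraint: significance at level α/m requires n_perm ≥ m/α − 1; the
  recovery tests use n_perm = 9,999 on a 320-cell grid. Degenerate cells
  (zero within-group variance everywhere) get F = 0, p = 1; an infinite
  observed F beats every finite permuted F.
* **Test cascade.** For each (site, measure, variable): Shapiro–Wilk per
  group and Levene (mean-centered) at 0.05 choose Student's t (both normal,
  homoscedastic), Welch's t (both normal, heteroscedastic), or
  Mann–Whitney U (any non-normal group, including constant groups where
  Shapiro–Wilk is undefined). Levene and the t-tests are computed from the
  textbook formulas (validated against scipy to 1e-12 in tests); Shapiro
  and Mann–Whitney come from scipy. The default observation unit is the
  stimulus-level feature row — matching the analysed "extensive,
  stimulus-based data set", and acknowledged as pseudoreplicated since
  stimuli within a participant are not independent; `unit="participant"`
  averages within participant first and is the statistically conservative
  alternative. BH-FDR is applied to the p-values pooled over the whole
  cascade by default (per-variable pooling available); the realized
  adjusted alpha (the largest passing p) is reported rather than
  hard-coding any particular value. Cohen's d uses the pooled-SD formula
  and is reported signed; tables print |d|.
* **Permutation count** defaults to 1,999 (unstated in the source
  material); type-I calibration at α = 0.05 is verified by simulation.

## The SOM classifier

Features per stimulus: the per-channel relative band powers and brain rate,
concatenated over retained channels and standardized with train-set
center/scale. The map is a 6 × 6 hexagonal grid (odd rows offset by ½,
row spacing √3/2) trained for 10,000 iterations: sample a training row,
find the best-matching unit, move every unit within the current radius
toward the sample (bubble neighborhood — all-or-nothing; Gaussian
available). Learning rate decays linearly 0.05 → 0.01 and the radius from
the ⅔ quantile of pairwise unit distances to 0 — the defaults of the
standard R implementation of Kohonen maps, which the study cites. The
codebook is initialized from a seeded sample of training rows. Training is
unsupervised; units then take the majority text-type label of the training
rows they capture, and prediction returns the BMU's label (an unlabeled
BMU falls back to the nearest labeled unit by grid distance, codebook
distance breaking ties). The 70/30 split assigns whole participants by a
seeded shuffle, choosing the participant prefix whose row count is closest
to the 70 % target — with 30 participants × 45 rows this hits 945/405
exactly.

Under the 120/15/15 design a majority-class predictor scores 0.8; the
zero-effect control in the end-to-end tests checks held-out accuracy does
not *exceed* that rate by more than 0.05 (the participant-leakage guard).
It can fall somewhat below 0.8 when sampling noise hands minority labels
to a few units.

## Problem sizes in tests

Unit and recovery tests run on reduced designs chosen as the package's
test-bed configuration: 8–12 channels (a labeled subset of the montage),
6–20 participants, 2–3 trials, 4–6 s stimuli, with group sizes scaled
proportionally from the study's (`scaled_group_sizes`). The generator's
*defaults* remain the full study design. The acceptance script runs the
printed-number recomputations at their true sizes (1,350 rows, 930 tests,
150-stimulus schedules) and the simulation-based rates on the reduced
designs.

## Known limitations

* The cascade's stimulus-level default is anticonservative
  (pseudoreplication); use `unit="participant"` for inference-grade runs.
* The component scorer is a heuristic, not a trained classifier; it is
  calibrated on the generator's artifact model and will not match a
  trained model's behavior on real EEG.
* The grid ANOVA's Bonferroni family and permutation scheme are two of
  several defensible choices; both are configurable, and the defaults are
  the stricter readings.
* Channel-flat signal topography means scalp-localization behavior
  (which channels carry an effect) is only exercised through explicit
  channel-subset effects.
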