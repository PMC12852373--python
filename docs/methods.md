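# Methods

This document specifies the computational methods implemented in `eegcoh`:
the synthetic EEG model, the preprocessing chain, the coherence features,
the wrapper-based feature selection, the evaluation protocol, and the
cross-domain validation tools.

## 1. Problem setting

The package studies a biomarker-discovery workflow for two-group
(case/control) resting-state EEG: can a small set of band-limited
inter-channel coherence features, selected by a wrapper search, classify
held-out subjects — and can the whole procedure be audited end to end?
Because clinical EEG is restricted, the package ships a generative model
with *planted*, analytically known coherence structure, so every stage has
a ground truth to be tested against.

## 2. Montages

The canonical sensor space is the 19-channel 10-20 clinical montage in the
fixed order

```
Fp1 Fp2 F7 F3 Fz F4 F8 T3 C3 Cz C4 T4 T5 P3 Pz P4 T6 O1 O2
```

All pairwise feature indexing is derived from this order, giving
19·18/2 = 171 unordered channel pairs.  A 64-channel 10-10 montage is
provided for cross-domain experiments; the legacy/modern label equivalences
T3/T7, T4/T8, T5/P7, T6/P8 are resolved explicitly when a 64-channel
recording is down-selected to the 19 canonical sensors
(`transfer.map_montage`).

## 3. Synthetic cohort model (`synthetic`)

Each subject is a multichannel recording (default 170 s at 500 Hz; the
acceptance runs use 250 Hz for speed) in microvolts composed of:

- **1/f background** — independent per channel, amplitude spectrum
  `max(f, 1)^(-1/2)` (exponent configurable), normalised analytically to
  `background_rms` = 20 µV.
- **Alpha rhythm** — an independent Gaussian spectral bump at 10 Hz
  (`alpha_rms` = 10 µV).
- **Power line** — a common-phase 50 Hz sinusoid (5 µV RMS).
- **Blink transients** — raised-cosine pulses (0.3–0.5 s, 90 µV) on
  Fp1/Fp2 at 10 events/min.
- **Planted in-band coherence** — the group effect, described next.

### Planted coherence

For a shared source `s` and independent noises, `x = √v·s + √w·n₁`,
`y = √v·s + √w·n₂` have magnitude coherence exactly `v/(v+w)`
(`plant_coherence_variances`).  For a *set* of pairs sharing channels this
generalises to linear mixing: the in-band spectral content of the effect
channels is multiplied by the Cholesky factor of a target correlation
matrix, so the planted coherences equal that matrix's entries in
expectation.

The target matrix cannot set the five default signature pairs
(Fz-Cz, Pz-P4, Fz-C3, Cz-P4, Cz-Pz) to a high value while keeping every
other pair at zero — positive semi-definiteness forces coherence onto
pairs that are adjacent in the pair graph (with Fz-Cz = Cz-Pz = 0.8, the
pair Fz-Pz must exceed 0.28).  The generator therefore completes the pair
graph by the shortest-path product rule (`coherence_completion`), which for
tree/chordal graphs is PSD with the listed entries exact.  Crucially, the
completion is evaluated at the *stronger* of the two group targets and
used for **both** groups, so these structurally forced "spillover" pairs
carry (almost) no group information; only the listed pairs differ between
cases (0.8) and controls (0.3).

### Temporal state fluctuation

Resting-state coupling is non-stationary, and a biologically inert
generator (constant coherence per subject) makes the classification task
trivially easy from any single pair.  The generator therefore redraws the
planted values every `coh_block_s` = 30 s.  Because coherence is bounded
in [0, 1], an additive normal fluctuation around a high target is
physically impossible (it either truncates, biasing the realised mean, or
piles mass at a ceiling, collapsing variability); the fluctuation is
modelled in **Fisher-z space** (`arctanh`, the standard
variance-stabilising transform for coherence): block value =
`clip(tanh(μ + coh_sd·z), 0.05, 0.95)` with `z ~ N(0,1)` i.i.d. per pair
and block, `coh_sd` = 0.3 in z-units.  The location μ is solved
numerically so the clipped-tanh mean equals the group target exactly
(`state_jitter_location`).  A constant z-space SD compresses near 1, so
cases (0.8) fluctuate with coherence SD ≈ 0.11 and controls (0.3) with
≈ 0.20 — strong coupling is naturally more stable.  The in-band component
is mixed blockwise in the time domain, so each 30 s analysis section sees
its own coherence state.  Two implementation details matter:

- The clip ceiling 0.95 keeps jittered hub pairs geometrically compatible
  with the fixed spillover entries (two triangle edges near 1 would force
  the third above them, triggering the PSD repair); the tanh tail makes
  this clip rare, so it barely perturbs the corrected mean.
- A fraction `coh_subject_rho` of the jitter variance can be made a stable
  subject trait.  The default is 0 (pure state noise): subject-trait
  variance makes individual subjects persistently cross the group
  boundary on individual pairs, which actively penalises recovering the
  full signature (a crossed subject is crossed in every section).

The planted band is widened by `band_margin_hz` = 1 Hz on each side — the
main-lobe half-width of the 1 s Hann window used downstream — so the
analysis bins at the band edges see the full planted coherence rather than
a leakage-diluted value.

Sex is assigned independently of group (`female_fraction` = 0.5), making
it a non-confounded covariate for subgroup reruns.

## 4. Preprocessing (`preprocess`)

1. Discard the first 10 s (settling/setup transient).
2. 50 Hz IIR notch (quality 30), zero-phase (`filtfilt`).
3. 0.5–44 Hz band-pass: 4th-order Butterworth high- and low-pass,
   zero-phase (`sosfiltfilt`).
4. Tile into exactly five non-overlapping 30 s sections (recordings must
   clean to ≥ 150 s).
5. Class balance: every case contributes all 5 sections, every control a
   random 3 of 5 (`balanced_sample*`, audited and seeded).  Note this rule
   balances *sections* only when the cohort has roughly 3 cases per
   5 controls; on an equal-size cohort it manufactures a 5:3 training
   imbalance, so equal-size cohorts should be sampled accordingly when
   section balance matters (e.g. null-calibration studies).
6. Train/test splits are **always at the subject level** (stratified,
   ceil-rounded 10 % test fraction, largest-remainder allocation across
   groups).  `LeakageError` is raised if any subject ever appears on both
   sides.

`filter_response` returns the analytic magnitude response of the full
zero-phase chain (each stage's response squared, forward-backward) and
serves as the oracle for filter tests.

## 5. Coherence features (`connectivity`)

Each 30 s section is cut into thirty 1 s epochs.  Per epoch and channel a
Hann-windowed rFFT gives single-taper spectra on a 1 Hz grid.  The
magnitude coherence of a pair is

```
C(f) = |Σₑ Sxy,ₑ(f)| / sqrt(Σₑ Sxx,ₑ(f) · Σₑ Syy,ₑ(f))
```

— cross- and auto-spectra are **averaged over epochs before** the ratio;
the per-epoch ratio would be identically 1 for single-taper spectra.

Band features are arithmetic means of `C(f)` over the integer bins of
delta [1,4), theta [4,8), alpha [8,12), beta [12,30), gamma [30,40]
(half-open bands; the last is closed).  The 171 pairs × 5 bands = 855
features are ordered pair-major (lexicographic in the canonical channel
order) and band-minor, named `"Fz-Cz:gamma"` etc.

## 6. Feature selection (`selection`)

Candidate subsets are scored by a **wrapper**: repeated subject-level
k-fold cross-validation (10 repeats × 10 folds = 100 fits) of an RBF
support-vector classifier (γ = 5.1053, C = 1), the score being mean
section-level validation accuracy.  Folds partition *subjects* (stratified
by group, round-robin after a seeded shuffle); fold membership is seeded
identically across candidate evaluations so subset comparisons are paired.

Features are left on their native [0, 1] coherence scale by default: the
default RBF width is calibrated to that scale, and z-scoring (available
via `standardize=True`) would rescale the kernel geometry out from under
it.

The search is classic sequential floating forward selection (SFFS): add
the candidate with the best wrapper score, then repeatedly drop a feature
whenever the reduced subset beats the best score previously recorded at
that size.  Once a subset classifies every validation section correctly
the accuracy criterion stops discriminating and exact ties are
unavoidable; they are broken by the subset's mean per-feature Fisher
discriminant ratio `(μ₁−μ₂)²/(σ₁²+σ₂²)` — the classic hybrid
filter-wrapper criterion, preferring equal-error subsets whose features
carry more class separation — and only then by the lower canonical
feature index.  The
default candidate pool is the 36 gamma-band pairs within the 9-sensor
central ROI (F3, Fz, F4, C3, Cz, C4, P3, Pz, P4).  The operating size is
chosen by a one-standard-error rule over the recorded sizes.

## 7. Evaluation (`evaluate`)

The final RBF-SVM is trained on the balanced training sections and scored
on **all five** sections of every held-out subject: accuracy, precision,
recall (positive class "case"), ROC-AUC from decision values (oriented so
larger = "case"), and the confusion table.

- **Significance** — subject-level label permutation: training labels are
  shuffled at the subject level, the balanced sample is rebuilt (it
  depends on labels), the classifier refit, and the untouched test
  sections rescored; `p = (1 + #{null ≥ observed}) / (1 + B)`.
- **Calibration** — Platt-style sigmoid probabilities via internal 5-fold
  CV; Brier score and expected calibration error over 10 equal-width bins.
- **Subgroup rerun** — the pipeline re-runs unchanged on a covariate
  filter (e.g. females only).

## 8. Interpretation (`shapley`, `interpret`)

Feature importance uses Shapley values of the decision value under the
interventional masking game `v(S) = mean_b f(x_S, b_{\S})` over a seeded
training-data background.  `exact_shapley` enumerates all coalitions
(oracle, d ≤ 20); `kernel_shap` solves the Shapley-kernel weighted
least-squares system with the empty/full coalitions imposed as
constraints — with exhaustive proper coalitions (d ≤ 15) it reproduces the
exact values; for larger d it subsamples coalitions.  Both satisfy local
accuracy by construction.  Global importance is the mean absolute Shapley
value over explained samples.  A t-SNE embedding of the selected features
is provided for reporting only.

## 9. Cross-domain validation (`transfer`)

- `map_montage` — down-select 64-channel 10-10 recordings to the 19
  canonical sensors (legacy/modern names resolved).
- `fold_sweep` — stratified subject-level CV of a fixed signature for
  every fold count k = 2..24; with n subjects the average training size is
  n(k−1)/k, so the sweep doubles as a learning curve, summarised by an OLS
  trend line of score against training size.
- `TrAdaBoostClassifier` — instance-transfer boosting: source and target
  samples start uniformly weighted; each round fits the weighted base
  learner, measures the weighted error εₜ on the target only, multiplies
  misclassified source weights by the fixed factor
  `β = 1/(1+sqrt(2 ln n / N))` and divides misclassified target weights by
  `βₜ = εₜ/(1−εₜ)`.  εₜ ≥ 1/2 stops the loop; εₜ = 0 is clamped to
  1/(2m).  Prediction is a vote over the last ⌈N/2⌉ rounds weighted by
  `ln(1/βₜ)`.

## 10. Reproducibility

Every stochastic step takes an explicit seed; subject data derive from
`SeedSequence([cohort_seed, sha256(subject_id)])`, so a subject's
recording is independent of generation order.  All deliverable outputs are
text (JSON/CSV); EDF is used for recording interchange.

## Limitations

- The generator's PSD repair (eigenvalue clipping) still slightly biases
  hub-pair coherences on blocks where the jittered entries are
  incompatible with the fixed spillover entries; the mean-corrected jitter
  removes the dominant clipping bias but not this residual.
- Spillover pairs are not exactly group-neutral under jitter (mean group
  difference ≲ 0.01), a small but nonzero leakage of the effect into
  unlisted pairs.
- Sampled (d > 15) kernel SHAP is approximate; the exhaustive and exact
  paths are the tested oracles.
- The permutation test freezes feature selection; p-values quantify the
  classifier given the signature, not the full discovery procedure.
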