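# Methods

This note documents the models, estimators and design choices behind
`quspred`, the assumptions they rest on, and what the synthetic substrate
does and does not establish about clinical data.

## RF simulation

The simulator produces pulse-echo frames of a 2-D random scatterer field
under a linear-array geometry. Each scan line (element pitch 0.3 mm by
default) accepts the scatterers within ±pitch/2 laterally, weighted by a
Gaussian beam profile (σ = pitch/2). A scatterer at depth z contributes a
weighted impulse at the round-trip delay sample `round(2z/c · fs)`; the
impulse train is filtered in the frequency domain with the zero-phase
transfer

    H_z(f) = P(f) · f² · √FF(f) · 10^(−2 α f z_cm / 20),

where `P(f)` is the Gaussian amplitude spectrum of the pulse (6 MHz
centre, 0.6 fractional −6 dB bandwidth, 40 MHz sampling by default),
`f²·√FF` is the amplitude-domain Gaussian-form-factor backscatter model
(so the power spectrum follows the model that is later fitted), and the
last term is the two-way attenuation accumulated to the segment depth,
applied per 1 mm depth segment. Per-scatterer amplitude is
`10^(AAC/20)/√density`, which makes the expected power spectrum — and
hence the fitted AAC — independent of the scatterer count.

Attenuation bookkeeping: α in dB/cm/MHz is one-way, so the round-trip
power-spectrum loss is `2 α f z` dB. The same constant is used in
simulation, in the spectral-difference ACE estimator and in the point
compensation, which is what makes the apply→estimate→correct chain an
identity on synthetic data.

At 60 scatterers/mm² (the default; ≈6 per resolution cell) the envelope
statistics are near- but not fully Rayleigh; the speckle-SNR property test
uses 400/mm², where the mean/SD ratio converges to √(π/(4−π)) ≈ 1.913.
The simulator deliberately omits diffraction, elevational beam structure,
nonlinearity and frequency-dependent beam width; the reference-phantom
division cancels the (shared) pulse spectrum, which is the property the
pipeline relies on, so passing tests demonstrate estimator correctness
under the stated model, not robustness to clinical system effects.

## Reference phantom

The reference phantom is simulated with α = 0.5 dB/cm/MHz and
near-Rayleigh scatterers (a_eff = 5 µm, AAC = 0 dB). Its per-depth
spectrum is averaged over the full lateral aperture before division, the
standard variance-reduction practice. Normalized spectra are converted to
apparent backscatter spectra by adding back the reference's known model
before form-factor fitting.

## Attenuation estimation and compensation

The spectral difference method regresses, per frequency, the dB ratio of
sample to reference spectra against block depth; the per-frequency decay
rates are then regressed through the origin against frequency, giving the
excess slope Δα, and ACE = α_ref + Δα. One ACE is produced per core ROI
(it needs a depth span; default minimum 10 mm).

Point compensation adds `2 (ACE − α_ref) f z` dB to each block's
normalized spectrum. The overlying path z defaults to the full depth from
the transducer face (`path_mode="surface"`), which is exact when the
medium above the block shares the core's attenuation — true for the
synthetic phantoms and the assumption a single local ACE supports. The
alternative `"roi_top"` compensates only the path below the ROI's
shallowest row; it leaves the overlying tilt uncorrected, which we
measured to bias ASD high by tens of percent on homogeneous phantoms, so
it is not the default.

## Backscatter model fitting

The fit minimizes the RMS dB residual between the apparent backscatter
spectrum and `AAC + 40 log₁₀ f + 10 log₁₀ exp(−0.827 k² a_eff²)` (Insana–
Hall Gaussian form factor; f⁴ expressed with f in MHz, the constant being
absorbed by the reference-relative AAC). Since AAC enters as a pure dB
offset, it is closed-form per candidate a_eff; a_eff is searched on a
1 µm grid over [1, 150] µm with Brent refinement (scalar path) or
parabolic interpolation (vectorized parametric-imaging path). Solutions at
the grid edge are flagged but returned.

Conditioning depends on ka: at 6 MHz a 25 µm effective radius spans
ka ≈ 0.4–1.0, where the form-factor curvature over the band is only a few
dB and single-block estimates are intrinsically noisy (spatial CoV near
80 % at our block size) — a physical limitation, not an estimator defect;
recovery of ROI-level means and of the ordering between media remains
reliable, and for larger scatterers (a_eff ≳ 60 µm) per-block maps are
smooth (CoV ≈ 10–18 %). Zero-noise spectrum-level round trips recover ASD
to well under 1 %.

## ROI geometry and textures

Margins are built by exact Euclidean distance transform in physical mm
(anisotropic pixels supported): a pixel belongs to the margin when its
distance to the core lies in (0, thickness]. Blocks (2 mm, 80 % overlap,
i.e. 0.4 mm lattice step) are anchored at the mask's bounding box and
kept when ≥ 50 % of their area is inside the region (`min_inside`,
configurable); a block also meeting that threshold on the core is assigned
to the core, so regions are disjoint.

Textures are computed on the block-lattice parametric image at its native
resolution: min–max quantization into 16 grey levels, one pooled symmetric
GLCM over the four distance-1 offsets (0°, 90°, 45°, 135°), and the four
Haralick features CON, COR, ENE, HOM. Pairs touching invalid lattice nodes
are excluded. Constant regions yield the degenerate vector CON = 0,
ENE = HOM = 1 with COR recorded missing. Pooling offsets into one matrix
(rather than averaging per-offset features) was an open choice; pooling is
simpler and exactly testable against pair enumeration.

## Feature table

61 QUS features per patient: {MBF, SS, SI, ASD, AAC} × {core, margin} ×
{MEAN, CON, COR, ENE, HOM}, plus CMR and CMCR per parameter, plus ACE
(core only, no parametric image). CMR = mean_core/mean_margin and
CMCR = |mean_core − mean_margin| / √(σ²_core + σ²_margin), the SNR/CNR
analogues, computed on the block-value populations; both are pluggable so
alternative definitions can be swapped. Plane aggregation is an unweighted
mean, missing-aware (a feature is missing only if missing in every plane).
ER/PR/HER2 can be appended as 0/1 columns.

## Classification

- Feature ranking: per feature, Shapiro–Wilk at α = 0.05 in each class;
  t-test (pooled variance) if both classes pass, Mann–Whitney otherwise;
  one-tailed in the observed direction; features sorted by ascending p
  with a name tie-break for determinism.
- Sequential forward selection: greedy scan in rank order; a candidate is
  kept only on a strict LOOCV-accuracy improvement (ties keep the smaller
  model). By default ranking and selection run once on the whole table —
  the classical procedure — with `selection="nested"` recomputing both
  inside every training fold for a fully leakage-free estimate. For the
  SVM, hyperparameters are held fixed during the selection scan and tuned
  only for the final model, keeping the grid search tractable.
- Classifiers: FLD (scikit-learn LDA), RBF SVM (C ∈ 2^{−5..15},
  γ ∈ 2^{−15..3}, log₂ steps of 2, chosen by inner LOOCV on the training
  fold), and the distance-weighted k-NN with W_i = 1/(d_i + 1e−8) on
  z-scored features (in-fold statistics), k over odd values 1–11 by inner
  LOOCV, smaller k on ties. The k-NN posterior is the weighted vote ratio;
  SVM decision values are squashed through a logistic for a posterior-like
  score (monotone, so AUC is unaffected).
- Metrics: sensitivity/specificity/accuracy in percent from the confusion
  counts; AUC as the midrank Mann–Whitney statistic; 95 % CI from 1000
  patient-level bootstrap resamples (single-class resamples redrawn);
  group separation assessed by the same normality-dependent two-sample
  test applied to the posteriors.

A note on attainable performance: with a 3σ mean separation and 42/14
priors the Bayes rule itself reaches only ≈ 94.5 % accuracy and an AUC of
Φ(3/√2) ≈ 0.983, and LOOCV on permuted labels is slightly pessimistic
(null AUC mean below 0.5). The acceptance tests therefore compare means
over repeated cohorts/permutations against these computed bounds rather
than against round numbers.

## Survival

Kaplan–Meier estimation and the 1-df log-rank test are delegated to
`lifelines` behind the module surface; ties between events and censorings
follow the events-first convention. Stratification can use recorded groups
or classifier predictions (every record must have a prediction). The
log-rank p-value is validated against a 10⁴-sample permutation null in the
tests. Five-year truncation, when used, is presentational only.

## Synthetic demo study

`run_pipeline` simulates a cohort (default 7 good / 3 poor responders,
3 planes each, 32 mm depth × 64 lines) in which tumour-core acoustic
properties depend on the hidden class — good: a_eff 25 µm, AAC 0 dB,
α 0.7 dB/cm/MHz; poor: a_eff 40 µm, AAC 3 dB, α 1.0 dB/cm/MHz; shared
background tissue (30 µm, 1 dB) outside the core — with per-patient
jitter, class-dependent exponential survival (0.004 vs 0.03 events/month,
20 % censoring) and Bernoulli molecular markers. These class contrasts are
deliberately strong: the demo verifies plumbing and determinism at desk
scale (it finishes in about twenty seconds per run on one CPU), not
clinical effect sizes, and its survival log-rank test on ten patients is
weakly powered. The per-(margin, classifier) report mirrors the margin
sweep {3, 5, 10} mm when configured; the persisted report omits wall-clock
time so identical configurations yield identical bytes.

## Known limitations

- No diffraction, focusing or elevational beam modelling; the reference
  division is exact in simulation by construction.
- Single ROI-level ACE (no per-block attenuation maps), matching the
  one-value-per-core design.
- ASD/AAC per-block maps are noisy at small ka (see above).
- The one-tailed ranking direction is taken from the observed difference,
  so under the null its p-values are uniform on (0, ½); tests account for
  this.
- Survival handling is nonparametric only (no Cox models, no competing
  risks).
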