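# Methods

## The model and its assumptions

The pipeline treats two-group discrimination of urine ¹H-NMR profiles as a
supervised latent-variable problem. After preprocessing, the data are a
samples × buckets matrix X (unit-variance scaled) and a class vector
y ∈ {BPH, PCa} encoded +1 (PCa) / −1 (BPH) and centred. OPLS-DA assumes the
class-predictive variation lies along a single latent direction and that
systematic variation uncorrelated with the class (diet, osmolality
residuals, instrument drift) can be removed first. Each orthogonal
component is estimated on the current matrix as w_o ∝ p − (wᵀp)w with
w ∝ Xᵀy, which makes every orthogonal score exactly uncorrelated with the
encoded class (tᵀ_o y ∝ wᵀ_o w = 0); the matrix is deflated and a single
predictive PLS component is fitted to the residue. The regression vector b
composes the deflation with the predictive component, so predictions are a
linear map of the scaled buckets and coefficient-based variable selection
is well defined.

Model quality is never judged on the training fit alone: R²Y measures fit,
Q²Y (stratified sevenfold CV, scaling refit inside each training fold)
measures prediction, the 100-label-permutation test builds the null for
both, and CV-ANOVA converts the PRESS reduction into an F-test p-value.
This mirrors the standard SIMCA-style validation battery for metabolomic
OPLS-DA models.

## Preprocessing choices

- **Bucket tiling.** Half-open [low, high) buckets tiled from the low-ppm
  end; a bucket's value is the *sum* of grid intensities inside it
  (area-proportional, conserves total signal). Any bucket overlapping an
  excluded region (water 4.55–5.09, urea 5.52–6.10 ppm) is dropped whole,
  keeping retained buckets uniform. With 0.01 ppm buckets over 0.15–9.50
  this gives 935 − 54 − 58 = 823 variables; at the fine 0.001 grid the same
  mask leaves 8230 buckets, and the exclusion edges land on 0.01 ppm
  boundaries so 10:1 rebinning reproduces 823 exactly with no partial
  buckets. Trailing partial groups at a segment end (possible for other
  widths) are kept as narrower buckets.
- **Alignment.** A deliberately simple cluster-style aligner: the reference
  sample maximizes mean correlation to all others; within each contiguous
  (unmasked) bucket segment every other sample is shifted by the
  integer-bucket lag maximizing the *unnormalized* overlap
  cross-correlation (normalized correlation is treacherous for short
  overlaps), the lag capped at min(max_shift, len/4) and ties resolved
  toward the smaller |lag|; the segment is then split at the widest gap
  between reference peaks (local maxima above median + 3·1.4826·MAD) and
  both halves are aligned recursively (minimum segment 20 buckets, depth
  ≤ 12). Shifted-out buckets are zero-filled, so per-sample totals are
  conserved up to edge effects. On the default jittered cohort this
  reduces mean per-peak position variance from ≈8.5 to ≈0.13 buckets².
  This is a stand-in at the contract level for published
  hierarchical-cluster peak aligners, not a re-implementation of any of
  them.
- **PQN.** Rows are integral-normalized to the cohort-mean total, the
  reference is the element-wise median spectrum, quotients are taken over
  buckets with positive reference, and each row is divided by its median
  quotient. The reported per-sample dilution estimate is the *combined*
  factor actually divided out of the raw row — the median of
  (raw row / reference) — which is the quantity comparable with a true
  dilution. Note the cohort-mean convention means rescaling one input row
  rescales the whole normalized cohort by a single global constant; all
  between-sample structure is invariant.
- **Scaling.** Mean-centre, divide by SD (n−1 denominator); zero-variance
  buckets are dropped with a logged warning. Inside cross-validation the
  scaling is refit on each training fold by default — a deliberate
  strengthening against leakage over fitting the scaler once on all data
  (the classic workflow's behaviour); both behaviours are selectable.

## The synthetic cohort generator

The generator emulates 500 MHz CPMG urine spectra at the level the
pipeline's statistics can see, with defaults chosen once as the study
conditions:

| parameter | default | rationale |
|---|---|---|
| group sizes | 51 BPH / 64 PCa | the study's cohort sizes |
| ppm grid | 0.15–9.50, step 0.001 | matches the fine bucketing scale |
| lineshape | area-parameterized Lorentzian, truncated at ±50 linewidths | standard NMR lineshape, cheap to evaluate |
| linewidth | 0.0015 ppm (urea 0.03) | well-shimmed small-metabolite lines at 500 MHz |
| base concentrations | discriminants: reported BPH group-mean intensities; background: creatinine 100, urea 60, hippurate 40, citrate 30, TMAO 25, … | urine spectra are dominated by these resonances |
| fold changes (PCa/BPH) | BCAA 1.094, glutamate 1.060, dimethylglycine 0.835, glycine 0.880, pseudouridine 1.116, U1 0.652, fumarate 0.879, 4-imidazole-acetate 0.774 | ratios of the reported group means |
| concentration variation | log-normal, sd 0.2 (log scale) | positive-valued inter-subject biology |
| dilution | log-uniform on (0.5, 2.0) | the variation PQN is designed to remove |
| shift jitter | per-sample, per-metabolite Gaussian, sd 0.003 ppm, capped ±0.01 | gives alignment real work at the 0.001 ppm scale |
| baseline | amplitude 5, ~3 ppm-period sinusoid, random phase | slow residual baseline after upstream correction |
| noise | Gaussian, sd 2 per grid point | high-SNR modern spectra |

All draws come from one `numpy` generator seeded by the config, so a cohort
is bit-reproducible. The `GroundTruth` object (dilutions, concentrations,
shift offsets, in spectrum order) is the oracle for recovery tests.

What the generator does **not** emulate: J-coupling fine structure and
second-order multiplets, pH-dependent shift drift (jitter is random, not
systematic), T2 editing, peak-shape distortions, correlated metabolite
physiology, or contaminant signals. Passing tests therefore demonstrate
that the statistical machinery behaves correctly under known ground truth —
not that the discriminant metabolites would survive every complication of
real urine.

## Numerical choices and degenerate inputs

- Bucket-edge comparisons use a 1e−9 ppm tolerance; grid points are
  assigned to buckets by `searchsorted` with a 1e−12 nudge so boundary
  points land in the bucket whose low edge they sit on.
- Lorentzians are evaluated only within ±50 linewidths (99.36% of the
  area). With the default 0.0015 ppm linewidth and 0.001 ppm grid, discrete
  intensity sums additionally carry a ±1.8% position-dependent sampling
  (aliasing) term — integrals of sharp lines on a comparable-scale grid are
  accurate to a couple of percent, not machine precision.
- b_cvSE is the delete-one-fold jackknife SE,
  sqrt((g−1)/g · Σ_f (b_f − b̄)²): fold coefficients are computed on
  overlapping (g−1)/g subsets, so the naive SD of fold coefficients
  underestimates the standard error by roughly √g. Fold coefficients are
  mapped back to the input coordinate system (chain rule through the
  per-fold scaling) before the spread is taken. Variables with zero SE and
  nonzero coefficient are maximally stable and kept (logged).
- CV-ANOVA: F = ((SS_tot − PRESS)/ν₁)/(PRESS/ν₂), ν₁ = number of model
  components, ν₂ = n − ν₁ − 1; F is clipped at 0 (p → 1 for models no
  better than the mean), and PRESS = 0 returns p = 0. Under the null the
  p-value is therefore conservative (mass near 1), not uniform.
- Permutation intercepts are the value at |corr| = 0 of the least-squares
  line through the permuted (|corr|, R²) / (|corr|, Q²) points plus the
  original point at |corr| = 1; the empirical p uses the add-one
  convention (1 + #{Q²_perm ≥ Q²_orig})/(n_perm + 1).
- Mann-Whitney U: exact null when combined n ≤ 20 with no ties, otherwise
  normal approximation with tie and continuity corrections (scipy).
  Identical groups give p = 1; groups smaller than 2 are rejected.
- Hotelling T² limit: a(n−1)(n+1)/(n(n−a)) · F₁₋α(a, n−a) with a scores
  estimated from the data; flagging never excludes — exclusion is an
  explicit pipeline option.
- Stratified folds come from scikit-learn's `StratifiedKFold` with a
  config-derived seed; a degenerate split (single-class training set) is
  reshuffled up to 10 times and then rejected.

## Open design points, resolved

- **Model dimensionality** is never stated upstream; the default is 1
  orthogonal component, configurable, with R²Y/Q²Y retrievable per choice.
- **"Dividing each variable by 1/SD"** is read as dividing by SD — the
  surrounding sentence states unit-variance intent, and multiplying by SD
  would do the opposite.
- **Select-then-revalidate bias.** Revalidating after selection on the same
  samples is optimistically biased, so the pipeline always computes a
  nested-CV Q²Y with the selection redone inside each training fold. At the
  study scale (115 samples × 823 correlated buckets) the plain
  select-then-refit Q²Y on *null* cohorts stays near zero (median ≈ −0.01
  over 20 seeds), but the bias is severe for small uncorrelated matrices;
  both numbers are printed so the reader need not trust the benign case.
- **Outlier screening order**: PCA/T² screening runs after normalization
  and scaling (a dilution artefact should not look like an outlier);
  whether to exclude flagged samples is a config flag, off by default.
- **Univariate tests** run on PQN-normalized, *unscaled* intensities (unit
  variance scaling is a modelling device; integrated intensities in
  arbitrary units are what a metabolite table reports), with no
  multiple-testing correction by default to mirror the classic raw
  p < 0.05 rule; Benjamini-Hochberg is available behind a flag.

## Problem sizes used by the tests

The test suite simulates cohorts at the study scale (115 samples, 823
variables) for the end-to-end checks — permutation validity (100
permutations; 20 null cohorts), selection recovery, type-I error (200 null
cohorts for the univariate stage) — and smaller constructed matrices for
unit-level oracles (brute-force Mann-Whitney enumeration up to combined
n = 10, PLS1 equivalence on 50 random matrices, planted-direction PCA
recovery). The full suite runs in a few minutes on one CPU.

## Known limitations

- The aligner handles integer-bucket shifts only; sub-bucket
  interpolation is out of scope.
- OPLS-DA is strictly two-class; multi-class extensions and O2-PLS are
  non-goals.
- The reported statistics of the original patient cohort are not
  reproducible here because those spectra were never deposited; the
  synthetic cohort reproduces the *structure* of the analysis (variable
  counts, validation behaviour, effect directions), not its patient-level
  numbers.
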