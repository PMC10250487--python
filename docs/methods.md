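# Methods

This note documents the models, numerical conventions and design choices
behind `salmofuse`, and what its synthetic benchmark does and does not
establish.

## The problem and the workflow

Food-origin authentication from two complementary mass-spectrometry blocks:
a lipid fingerprint (binned ambient MS spectrum, negative mode) and a
trace-element concentration panel. Neither block alone identifies all five
provenance groups reliably; the workflow fuses them and classifies with
latent-variable discriminant models:

1. spectral parsing: background subtraction → lockmass recalibration →
   relative TIC threshold → 0.2 Da binning → TIC normalization;
2. element QC: internal-standard ratioing, CRM recovery, below-LOD
   filtering;
3. fusion (low- or mid-level);
4. classification (PLS-DA / OPLS-DA / LDA / k-NN / external RF, SVM) under
   stratified five-fold cross-validation;
5. marker selection via one-vs-rest OPLS-DA S-plots and VIP.

## Preprocessing conventions

* **Lockmass.** Single-point multiplicative recalibration: every m/z is
  multiplied by `reference / observed_lock` (reference 554.2615 Da, the
  leucine enkephalin [M−H]⁻ ion). This is the standard TOF drift model and
  exactly inverts a uniform relative drift, which is what the synthetic
  peak-list emitter applies.
* **Binning.** Half-open bins `[edge, edge + 0.2)` from m/z 100, giving
  exactly 5500 bins over 100–1200; labels are bin centers rounded to one
  decimal (a peak at 327.2324 lands in bin "327.3"). Binning conserves
  total in-range intensity exactly. Three of the eighteen shipped marker
  records carry printed bin labels inconsistent with this (or any uniform)
  0.2 Da grid; they are flagged `bin_discrepant` and the printed label is
  preserved rather than corrected.
* **Ion masses.** Deprotonated-ion mass = neutral monoisotopic mass minus
  one hydrogen *atom* (1.0078250319 Da), no electron-mass term: this
  convention reproduces 14 of the 18 published panel masses to ≤ 5×10⁻⁴ Da,
  which subtracting the electron mass as well does not. The four records
  that disagree by more than that under any standard convention are flagged
  `mass_discrepant` and shipped with both printed and computed values; the
  printed value stays authoritative for annotation, the computed one for
  validation. Atomic masses are the IUPAC most-abundant-isotope values;
  isotope patterns are out of scope.
* **Background subtraction** matches peaks within 0.01 Da (the raw-profile
  subtraction normally happens inside vendor software; the tolerance is a
  package choice) and clips at zero.
* **Min–max scaling** maps constant columns to 0 (a constant is
  uninformative and this avoids division by zero); stored extrema are
  re-applied to held-out data without clipping, so projected values may
  fall outside [0, 1].
* **Below-LOD values** are represented as zeros (matching the published
  element table's 0.00 entries), with the mask carried alongside so
  LOD/2-style substitutions remain possible upstream.

## Fusion

`compress_block` performs exact PCA by SVD after centering and per-block
scaling — Pareto (division by √sd) for the spectral block, the usual mild
shrinkage for MS data; unit variance for the element block, the default for
heterogeneous-unit panels. The retained count k is the smallest whose
cumulative explained-variance ratio reaches the threshold (default 0.85,
"≥" semantics, ties toward fewer), capped at min(n−1, p, 250); the 250 cap
accommodates the ~226-component regime of a 5500-bin block. Scores are
concatenated without reweighting by default (an optional per-block
retained-variance weighting exists); the concatenated columns carry exact
(block, component) provenance, and the stored centering/scaling/loadings
project held-out samples without re-fitting. Low-level fusion concatenates
min–max-scaled raw blocks under the same transform-reuse contract.

Because the raw score scales of the two blocks are unit-dependent, the
relative block weight in unweighted concatenation is arbitrary; with the
default scalings the element scores carry most of the numeric variance.
Balancing the blocks to equal total score variance was evaluated on the
synthetic benchmark and did not improve (it slightly hurt) classification,
so the spec'd "no reweighting" default stands.

## Latent models

* **NIPALS PCA**: deterministic initialization from the maximal-variance
  column, tolerance 1e-10, 500 iterations max; non-convergence is a logged
  warning, not an error. Per-component explained variance is
  ‖t pᵀ‖²_F / ‖X‖²_F.
* **PLS-DA**: NIPALS PLS2 on one-hot class indicators (classes sorted
  lexicographically), regression-mode deflation of X and Y, coefficients
  B = W (PᵀW)⁻¹ Cᵀ, prediction by argmax over predicted indicator columns
  with ties broken toward the lowest class index (logged). Default 25
  components, capped at min(n−1, p).
* **OPLS-DA**: for each orthogonal component the current X-loading is
  orthogonalized against an orthonormal basis of span(XᵀY) (QR). Deflation
  by orthogonal components leaves XᵀY unchanged, so one basis serves every
  extraction, and every orthogonal score is *exactly* uncorrelated with
  every class indicator — also in the multi-class, multi-Y case, which the
  classical single-y filter does not guarantee. The predictive part is a
  PLS2 fit on the filtered matrix (default n_classes − 1 components;
  one predictive component per binary contrast). X = T Pᵀ + T_o P_oᵀ + E
  holds by construction on the centered/scaled training data. One-vs-rest
  binary OPLS is used for S-plots, matching how the contrasts are defined.
* **Q²** is cross-validated by row-wise fold exclusion (default 7 folds,
  SIMCA convention; 5 on request for parity with classifier CV). For PCA,
  Q²(cum) = 1 − Π_a(PRESS_a/SS_{a−1}) with SS from the full-data fit; the
  held-out rows are projected onto fold-trained loadings, a documented
  approximation to element-wise cross-validation. For PLS,
  Q² = 1 − PRESS/SS(Y).
* **VIP** uses the normalized-weight form; mean(VIP²) = 1 holds exactly and
  is asserted in the tests.
* **LDA** uses a pooled within-class covariance with proportional priors; a
  singular pooled covariance raises an error that points at PCA-LDA, which
  chains a stored PCA compression before the discriminant.
* **k-NN** (default k = 5, Euclidean) breaks vote ties by the smaller mean
  distance among tied classes, then the lowest class index; distance ties
  resolve by training order (stable sort).
* **RF and SVM are not re-implemented**: `SklearnAdapter` plugs
  scikit-learn's implementations (ntree = 500, npredic/max_features = 15;
  RBF-SVM defaults) into the same fit/predict slots.

## Evaluation

Cross-validation re-fits *everything* — block scaling, PCA compression, the
classifier — inside each training fold. Published workflows that compress
once globally can leak held-out variance into the transforms and report
slightly higher rates; this implementation's CV numbers are therefore
conservative by design. Fold assignment uses stratified k-fold (plain
k-fold available; 522 rows into five plain folds gives sizes
105/105/104/104/104).

Outlier flagging combines Hotelling T² over model scores (F-based limit for
new observations) with a residual distance-to-model limit taken from the
empirical training-residual quantile. Each test runs at α/2 (Bonferroni) so
the union calibrates to ≈ α on training-like data — two tests at the full α
would flag ≈ 2α. Flagged replicates land in the confusion matrix's Outlier
column and count as incorrect for the overall rate (conservative; the
outlier count is also reported separately). Test samples are called by
majority vote over their non-outlier replicates (default 6); an all-outlier
sample is called "Outlier".

Element statistics: tie-corrected Kruskal–Wallis (chi-square tail;
all-identical data returns H = 0, p = 1 rather than erroring) and pairwise
two-sided Mann–Whitney with Holm correction — the nonparametric pairing
consistent with the KW framing, since the upstream analysis names neither
the pairwise test nor the correction. The chi-square tail agrees with the
exhaustive permutation null to ±0.02 in the significance region for groups
of about eight; in the far center of the distribution at such sizes the
asymptotic tail is visibly conservative, which the tests document.
`cv_anova` is labelled an approximation (F from CV-explained vs CV-residual
sums of squares); the label-permutation test on Q² returned alongside is
the recommended significance measure, with resolution 1/(N+1) at N
permutations.

## The synthetic generator

The generator defines the package's study conditions: five classes, default
100 samples per class, 5500 bins, 17 test samples × 6 replicates.

* **Elements.** Each (group, element) marginal is a log-normal pinned to
  the published median and IQR: μ = ln(median),
  σ = ln(Q3/Q1)/(2·z₀.₇₅). Zero inflation 0.55 where the printed median is
  0 (0.3 where only Q1 is 0); cells whose printed median/quartiles repeat
  the value 9223.37 are right-censored at that cap, read as an
  instrument/calibration ceiling. Three printed cells are internally
  inconsistent (a median outside its own IQR; an inverted quartile; a
  malformed number) and are repaired in the shipped table with the raw
  strings kept alongside. The closed-form bridge reproduces the quartile
  *ratio* exactly, so for cells whose printed quartiles are not
  geometrically symmetric about the median (several print Q1 = median) the
  implied IQR deviates from the printed difference — parameter-recovery
  checks therefore assert medians everywhere but IQRs only for
  near-symmetric cells.
* **Spectra.** I.i.d. log-normal baseline per bin (scale 100, log-sd 0.3)
  with a per-sample log-normal TIC factor (log-sd 0.2) and multiplicative
  class effects on the 18 marker bins: ×3 for the favored production type
  on the six production markers (wild ↑ 301.3/327.3/337.3,
  farmed ↑ 277.3/279.3/281.3), ×3 Alaska / ×2 Norway on 239.1, and ×2.5 on
  one class-specific bin each for the remaining panel so every group has a
  unique signature. The noise and effect sizes were fixed once as
  a realistic-looking regime for this kind of fingerprint and not tuned
  afterwards.
* **Replicates** of a test sample are independent draws from the class
  distribution — there is no shared per-sample random effect, so the
  replicate majority vote is exercised mechanically rather than
  realistically.
* A **null configuration** (`class_effects=False`) removes the marker
  effects and gives every class one shared element table; all classifiers
  then sit at 5-class chance in CV, which the tests assert.

### What the benchmark shows — and does not

Within-class independence across bins and elements is the generator's
biggest simplification: real fingerprints are strongly correlated, so their
leading principal components carry class structure, whereas here the 85%
variance threshold (capped at 250 components) retains mostly noise
directions. Two consequences, both documented in the tests rather than
hidden: the fused-pipeline PLS-DA five-fold CV rate on the default dataset
is 97–99% rather than a clean 100% — the residual confusion is genuine
overlap between the two simulated farmed Atlantic groups — and k-NN is not
handicapped the way it is on real correlated data, so the
"k-NN underperforms PLS-DA" ordering holds on average over replicate seeds
but can invert in a single draw. Passing tests establish the correctness of
the pipeline mechanics (transform reuse, no CV leakage, model identities,
oracle agreement), not field performance on real spectra.

## Benchmark sizes

The default acceptance computation uses 500 training samples × (5500 + 20)
features and runs five-fold CV with per-fold SVD compression in a few
seconds on one core; the test suite's heaviest fixtures are three such
replicates plus a 10⁴-per-class element-recovery draw, keeping the full
suite around a minute.
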