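# Methods

This note documents the models, the numeric conventions, and the design
choices made where the procedure admitted more than one reading. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and scaling

Expression matrices are features × samples; labels are −1/+1 with +1
mapped to the majority-count class (ties resolve to +1 so the pipeline
is deterministic on balanced data). Standardization is **per sample**
(column-wise, zero mean, unit variance with the p−1 denominator): this
is the reading under which the pairwise-distance analysis of the
overfitting bias is stated ("each sample is a zero-mean point with unit
standard deviation"), and it is fit-free, so there is no train/test
leakage in scaling. A per-feature axis switch exists for the equivalent
feature-scaling reading. Count data additionally support upper-quartile
scaling (divide each sample by its Q3/1000) and counts-per-million.

## Kernels and Gram-structure diagnostics

Five kernels: linear `x·x'`; Gaussian `exp(−‖x−x'‖²/2σ²)` with σ² = 1
("rbf") or σ² set to the total variation of the training samples
Σᵢⱼ‖xᵢ−xⱼ‖²/(m−1)² over ordered pairs including i = j ("rbf2");
quadratic `(1+x·x')²`; sigmoid `tanh(x·x'−1)` ("mlp", not positive
semidefinite — used deliberately to induce underfitting; no PSD repair
is attempted, and a singular dual system falls back to least squares
with a warning).

A square Gram matrix is classified as **identity_like** when every
off-diagonal magnitude is below ε = 1e−8 and the diagonal is within
ε of 1; **flat_like** when the entry range is below 1e−8 (covering the
all-ones sigmoid collapse); else **normal**. The thresholds sit far
below any meaningful kernel similarity yet far above float noise, and
are configurable. When the minimum pairwise squared distance exceeds
100, the rbf(σ²=1) off-diagonals are at most exp(−50) ≈ 2·10⁻²²,
which forces the identity classification — the overfitting mechanism in
closed form.

## LS-SVM conventions

The dual is the (m+1)×(m+1) saddle system with ridge `K + I/C` on the
diagonal block; μ = 1/C with C = 1 everywhere (no grid search, keeping
the α values comparable across cohorts with different skew). With
K = I the system solves in closed form: b = ȳ and αᵢ = (yᵢ−ȳ)/2, so a
test sample far from all training samples receives
sign(b) = the majority sign — the overfitting bias is a theorem, not an
observation, and the tests exercise it as such. A decision value of
exactly 0 maps to +1. LS-SVM α are dense; the signed-weight report
counts all |αᵢ| > 1e−12 with the class sign of sample i attached.

## DCA numeric choices

* **Boundary mode: periodization.** It is the only common DWT mode whose
  level-j coefficient length is exactly ⌈p/2ʲ⌉ and it preserves perfect
  reconstruction, giving the lossless limit (keep all components ⇒
  output = input to 1e−8) the tests rely on.
* **Per-level reconstruction.** The reconstruction is read as: restore
  each column's (sample's) mean, plus the rank-m approximation of the
  column-centered coefficient matrix. This is the unique
  shape-consistent reading of the mean-plus-factors reconstruction given
  loadings in sample space and scores in coefficient space, and it
  reduces to ordinary PCA denoising. The centering axis (column vs row
  means) is exposed as a switch; column is the default.
* **Rank rules.** Finest detail levels j ≤ τ = 2 keep a fixed number of
  components (m = 1, first PC — the setting used throughout the
  experiments); coarser details and the approximation keep the smallest
  m whose cumulative variance fraction reaches ρ = 0.95. ρ = 1 keeps
  everything. Defaults: db8, J = 7, requiring p ≥ 2⁷ features.
* **Out-of-sample transform.** The procedure is defined on a matrix, not
  per sample, and is silent on unseen data. Default is the transductive
  mode: test columns are appended to the stored training matrix, the
  transform re-runs jointly, and the test columns are extracted. This
  shares unlabeled test structure with the transform (never the labels)
  and is flagged in reports. An inductive mode freezes the per-level PCA
  score bases at fit time and projects test coefficients onto them.

## Bias classification rules

The verbal criteria ("accuracy close to the majority-count ratio",
"imbalanced sensitivity and specificity") are made numeric as a rule
cascade over fold-averaged metrics, the training-Gram structure and the
majority ratio r:

1. identity_like Gram, specificity ≤ 0.05, |accuracy − r| ≤ δ →
   **overfitting**;
2. flat_like Gram, accuracy ≤ 0.6 → **underfitting**;
3. normal Gram with sensitivity/specificity gap ≥ 0.30:
   accuracy ≤ r + δ → **explicit label skew**, accuracy > r + δ →
   **implicit label skew**;
4. else **none**, with δ = 0.025.

The skew rule is one-sided on purpose: an accuracy at or below the
majority ratio is the deceptive explicit form however far below it
falls, while only an accuracy clearly above the ratio earns the
implicit label. A two-sided window cannot reproduce the published
benchmark classifications for any single δ (the implicit kidney-cohort
case sits 0.0275 above its ratio while an explicit glioma case sits
0.0282 below its own). All thresholds are artifact choices, documented
here, and configurable per call. NaN is a value, not an error: any 0/0
ratio (e.g. NPR when nothing is predicted negative) is NaN and
propagates through fold averaging, matching how such results are
reported.

## Evaluation harness

k-fold CV (plain random partition by default), LOOCV, and Monte-Carlo
half-splits (exactly ⌈n/2⌉ training samples per repetition, or an
independent fair coin per sample with empty-sided draws redrawn;
500 repetitions by default). Metrics are averaged per fold with the
sample (n−1) standard deviation. All randomness flows from the scheme
seed. Stratified folds are off by default but available — small skewed
cohorts otherwise produce folds with no minority samples, which is
reported as NaN rather than hidden. A single-class training fold raises
a descriptive error. rbf2 resolves its bandwidth from each training
fold.

## Synthetic cohorts: what they emulate and what they do not

No generative model is published for the benchmark cohorts, so the
generators emulate exactly the properties the bias analysis rests on:

* **Distribution family** — normal intensities for array-like data;
  negative-binomial counts (mean/dispersion parameterization, variance
  μ + μ²/r, r = 2) with log-normal per-feature means for
  sequencing-like data.
* **Label skew** — presets reproduce the benchmark class counts
  (13 vs 34, 78 vs 72, 68 vs 475, 18 vs 516, 18 vs 512), majority
  labeled +1. The feature count defaults to 2048 (1024 for the
  miRNA-like preset) — a power of two satisfying the p ≥ 2⁷ wavelet
  constraint and large enough for the distance analysis, standing in
  for the 19 000–24 000 features of real cohorts.
* **Shared baseline** — a per-feature baseline common to all samples
  (SD 2 for normal data; the log-normal means for counts). This is what
  makes samples strongly correlated after standardization, saturating
  the sigmoid kernel into the flat Gram matrix observed on real data.
* **Signal amplification** — `amplify_to_min_distance` grows the
  feature count with noise features until the post-standardization
  minimum pairwise squared distance reaches its target (distances grow
  linearly with dimension for near-independent noise) and verifies the
  contract before returning.
* **The label-skew fixture** plants a smooth (low-frequency sinusoid)
  class contrast of amplitude 0.06 in unit-SD high-pass noise at a 1:4
  skew (16 vs 64 samples, p = 256). The noise concentrates in fine
  wavelet levels, the signal in coarse ones: at this signal-to-noise
  ratio the raw linear LS-SVM collapses toward the majority class while
  the DCA front end removes the fine-scale noise and restores
  separability — the label-skew conquest in miniature.

The generators do **not** emulate gene–gene correlation structure,
batch effects, platform-specific noise, or heavy-tailed outliers.
Passing tests therefore demonstrate the bias mechanisms and their
conquest under the stated statistical structure, not performance claims
on any real cohort.

## Biomarker ranking

Count data are first pushed toward normality by
Y = E(log(X+1))/var(log(X+1)): log-transform, center each sample column
by its mean, divide element-wise by that column's variance. The E(·)
term is read as centering ("adjusting the column with its mean") and
the quotient uses the variance literally rather than the standard
deviation; a z-score variant sits behind a flag. Features are then
ranked by the classic pooled-variance two-sample t-test on DCA true
signals (Welch available as an option); zero-pooled-variance features
get p = 1. Ranking uses raw p-values; a Benjamini–Hochberg column is
attached for information only. The top-k (default 3) true-signal
coordinates are exported for phenotype-separation plots.

## Problem sizes

Tests and the acceptance script run the full pipeline on the synthetic
cohorts above (47–543 samples, 256–2048 features) and on a
genome-scale decomposition check (p = 18 995), completing in seconds on
one CPU; feature counts are configurable up to real-cohort scale.

## Known limitations

Binary phenotypes only; no multi-class extension. The C-SVM quadratic
program is not implemented (the LS-SVM substitutes for it throughout).
The transductive DCA mode shares unlabeled test structure with
training; use the inductive mode when that is unacceptable. The
mlp kernel's indefiniteness can make the dual system ill-conditioned;
the least-squares fallback is reported via a warning.
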