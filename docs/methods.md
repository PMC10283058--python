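# Methods

This note documents the models implemented in `uromics`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Synthetic cohorts

The generator produces the cohort structure the downstream analysis
assumes, so that every stage is testable without any external data.

**Intensity model.** Log2-normal: for sample *s*, replicate *r*,
feature *f*,

    log2 I_fsr = baseline_f + shift_f(class_s) + bio_fs + batch_f,b(s) + eps_fsr

* `baseline_f` ~ N(12, 2) (metabolites) / N(11, 2) (peptides) log2 units —
  a broad dynamic range typical of urine fingerprints.
* `bio_fs` ~ N(0, `bio_sd_log2`), the between-subject biological spread;
  default 0.30 log2 (~23 % CV), a realistic urine-metabolome
  between-subject figure. Zero for the internal standards, which are
  spiked at fixed concentration.
* `batch_f,b` ~ N(0, `batch_sd_log2` = 0.25) per feature and batch. The
  two internal-standard channels instead share a single per-batch
  instrument-sensitivity shift, so their *ratio* cancels batch drift —
  that is exactly why paired spike-ins are used as a stability control.
* `eps_fsr` ~ N(0, σ) with σ = sqrt(ln(1+cv²))/ln 2, so the linear-scale
  technical CV equals `noise_cv` (default 0.15) exactly.

**Planted stepwise markers.** By default 10 metabolites (majority
down-regulated with disease) and 6 peptides (majority up-regulated),
mirroring the directional asymmetry seen in urine: metabolite loss with
nephron damage, peptide accumulation with reduced filtration. Each marker
receives monotone per-class shifts along HC → T2DM → early DKD → overt
DKD with per-transition increments `effect_log2fc × U(0.5, 1.5)`
(default mean increment 0.5 log2). The increments are feature-specific on
purpose: with identical increments all class mean vectors are collinear,
every linear contrast degenerates to a single axis, and the third cascade
layer (a middle class versus its neighbours) would carry no linear
information — unlike real marker panels, whose members emphasize
different stages. The grey-zone class sits a configurable fraction
(default 0.5) of the way along the T2DM → early-DKD increment, encoding
"biochemically on the way to DKD but UACR-negative"; the fraction is a
model assumption, not an estimate.

**Clinical covariates** are truncated normals whose bounds enforce the
KDIGO albuminuria categories by construction (HC/T2DM: UACR < 3 mg/mmol,
mALB < 30 mg/g, eGFR ≥ 60; grey-zone: mALB ≥ 30 with UACR < 3 and
eGFR ≥ 60; early DKD: 3 ≤ UACR < 30 with eGFR ≥ 60; overt DKD:
UACR ≥ 30, eGFR allowed below 60), with stage-trending means (eGFR
decreasing, UACR/mALB increasing).

**What is not emulated:** isotope envelopes, adducts, detector
saturation, retention/drift recalibration, missingness mechanisms other
than peak-detection failure, covariate–feature coupling (features depend
on class only), and real biological correlation structure between
features (features are independent given class). Passing tests therefore
demonstrate correctness of the statistical machinery under a known
generative model, not performance on real spectra.

**Spectrum emission** renders each replicate as a Gaussian-peak trace
(width 0.05 Da metabolite / 2 Da peptide; grid 0.01 / 0.5 Da) over a flat
baseline (offset 3, additive N(0,1) noise, clipped at zero). Peak pairs
closer than twice the width trigger an overlap warning.

## Preprocessing

**Peak picking.** A point is a peak when it is a strict local maximum and
its height *above the local baseline* exceeds `snr_threshold` (default 3)
times the local noise scale; baseline = sliding-window median, noise =
1.4826 × sliding-window MAD (window 101 points, clipped at edges). The
baseline-relative form is the field convention for S/N; a raw
intensity/noise ratio misbehaves on non-negative traces because the
rectified noise floor's MAD understates its upper tail. Note that on long
noise-only traces the rule still fires occasionally (the iid-Gaussian
rate is ≈0.0013 per interior point, plus MAD-estimation noise);
non-reproducible noise peaks are removed later by the presence filter.

**Alignment** pools all peaks, sorts by m/z and splits where the gap
between neighbours exceeds the tolerance — single-linkage clustering with
a cutoff. Defaults: ±0.05 Da (metabolites, reflector-mode-like absolute
error) and ±500 ppm (peptides, linear-mode mass-proportional error). Each
input peak maps to at most one feature; per cluster and sample the most
intense peak is kept.

**Normalization.** For each sample a monotone cubic (PCHIP) mapping is
fitted between the sample's and the reference's log2-intensity quantiles
at 9 evenly spaced probabilities (7 interior knots) and applied to all
observed values. A monotone Hermite spline is used rather than a natural
cubic spline because rank preservation within a sample is a hard
requirement and a natural spline through arbitrary monotone knots can
overshoot. Quantiles use the order-statistic (`lower`) definition, which
commutes with monotone maps and makes the operation exactly idempotent.
Reference options: per-feature median over all samples (default), over QC
rows, or an explicit sample. Samples with fewer observed features than
knots fall back to median scaling (logged). Features present in < 70 % of
rows are dropped; remaining missing values are imputed with half the
feature's minimum observed value. Replicates are averaged *after*
normalization so technical-replicate concordance is measurable on
normalized data.

**QC report.** Replicate Spearman (mean over all QC replicate pairs),
median per-feature intra-batch RSD of QC rows, inter-batch RSD of
per-batch QC means, and the RSD of the internal-standard ratio across all
rows, with pass flags (Spearman ≥ 0.8, RSD ≤ 25 %).

## Differential statistics

Tests run on log2 intensities (fold changes are then differences of
means). Welch's unequal-variance t-statistic is the default — group
variances differ by construction in real cohorts — with the pooled
Student form behind a flag. BH adjustment wraps
`statsmodels.stats.multitest` and rejects p-values outside (0, 1].
Degenerate zero-variance features are flagged rather than propagated as
NaNs. The stepwise set intersects the per-contrast strict q < 0.05 sets
over the adjacent-stage contrast family and also reports Venn-region
counts and an optional monotone-direction filter (whether "stepwise"
additionally requires a consistent direction is exposed, not imposed).
Clinical correlation uses Spearman by default (robust to skewed
covariates such as UACR) and flags |r| > 0.3.

## OPLS-DA

Implemented from the O-PLS algorithm: repeatedly, the PLS weight
w ∝ Xᵀy is computed, the loading of the current X is orthogonalized
against w to give an orthogonal weight, and the resulting component
(whose scores are exactly uncorrelated with the class code by
construction) is deflated from X; finally a single predictive component
is fitted to the deflated matrix. Binary coding is −1/+1; unit-variance
scaling is the default (flag to disable); with zero orthogonal components
the model equals single-component PLS1 identically. Deflation preserves
the total sum of squares, so R²X per component is well-defined. Q² is
1 − PRESS/TSS over stratified K-fold (default 7) held-out class codes.
The number of orthogonal components and the scaling are configurable;
defaults (1, unit variance) follow common chemometric practice.

## ML harness

Stratified 2:1 discovery/validation splits (per-class rounding keeps
counts within ±1 of the target). Hyperparameters are selected by
stratified 10-fold CV *on discovery data only*, with fixed documented
grids: SVM (linear C ∈ {0.1, 1, 10}; RBF C ∈ {1, 10}, γ ∈ {scale, 0.1}),
DT depth ∈ {3, 5, ∞}, Logi C ∈ {0.1, 1, 10}, KNN k ∈ {3, 5, 7, 9} (odd k
only, so votes cannot tie), LASSO C ∈ {0.01, 0.1, 1, 10}; NB and LDA have
no grid. Scores come from each model's native probability where defined,
else a logistic link on the decision value. For multi-omics fusion the
two blocks are concatenated after per-feature z-scoring within each block
(fitted on discovery rows), preventing the higher-variance block from
dominating. Evaluation metrics follow their standard definitions; κ uses
chance agreement from the marginals; AUC is the Mann–Whitney statistic
with ties counted ½.

## Diagnostic cascade

Three ordered binary layers: (1) HC vs all patients, (2) T2DM vs kidney
disease (grey + early + overt), (3) early DKD vs {grey, overt}. Each
layer is an L1-penalized logistic model selected over a 25-point
geometric λ path (floor ratio 0.01 when n < p, else 1e-4, following
glmnet) by stratified 10-fold CV deviance with the 1-SE rule (sparser
panels; `min` available). If the CV band reaches the intercept-only
model, the layer falls back to the min rule and then to the strongest
penalty with a nonempty panel — a weak layer then scores near-chance
honestly instead of aborting the whole cascade. Coefficients are folded
back to the raw feature scale so the serialized JSON model is a plain
linear scorer. Layers 2–3 train on the true labels of their in-scope
classes (training-time error propagation avoided; survivor-training
available by flag), while prediction is strictly sequential: a sample
stops at the first layer scoring below that layer's cutoff (ties routed
positive). Cutoffs use the Youden index on discovery scores (smallest
maximizing threshold on ties; the median score, flagged, when no
threshold is informative).

Terminal classes are {HC, T2DM, EARLY_DKD, DKD_OTHER}: the third layer is
binary, so grey-zone and overt DKD share the DKD_OTHER terminal; grey-zone
performance is reported separately as the fraction of grey-zone samples
routed past layer 2 (recognized as kidney disease rather than T2DM). The
permutation baseline for cascade performance permutes the evaluation
labels of the fitted model — refitting on permuted labels is not
meaningful here because the LASSO correctly selects the empty model under
the null.

## Networks and pathways

Biweight midcorrelation: median-centred values weighted by (1−u²)² for
|u| < 1, u = deviation/(9·MAD), normalized cross-product; Pearson
fallback when MAD = 0. Edge p-values use the Student-t approximation with
n−2 df; edges require |r| > 0.3 *and* p < 0.05. The pathway perturbation
(JG) score is a signed Stouffer aggregate Σ zᵢ/√k with
zᵢ = sign(log2FCᵢ)·|Φ⁻¹(pᵢ/2)| and p capped at 1e-300 — a documented,
swappable strategy chosen because the score must be signed, grow with
coherent perturbation (√k under duplication) and cancel under balanced
up/down changes. Enrichment is the one-sided hypergeometric upper tail on
(N, K, n, k) with BH adjustment across pathways; joint
metabolite + protein enrichment pools the two namespaces into a union
universe (no bundled pathway database — annotation is user-supplied GMT).

## Problem sizes used in the automated checks

Chosen once as study conditions: null calibration uses 100 two-group
cohorts (25+25, single batch and replicate — the t-test's nominal
i.i.d.-normal setting; replicate averaging on the linear scale and
per-feature batch shifts add small benign non-normality that is not the
object of that check); planted-marker recovery uses the default
501-sample cohort at seeds 1–10; the cascade check uses one 501-sample
cohort with a 2:1 split and compares grey-zone routing against a cohort
generated with the grey effect set to zero; the multi-omics comparison
uses 20 two-class cohorts (75+75) with 60+60 features and 10+10 planted
markers at effect 0.3, so each modality is informative but unsaturated;
QC checks use a 12-replicate QC sample at 10 % technical CV.

## Known limitations

* Feature independence given class means correlation-network results on
  synthetic data only exercise the machinery; planted co-regulation is
  limited to what the latent-factor test fixtures construct.
* The cascade's third layer separates a middle class with a linear
  scorer; its power depends entirely on how distinguishable the stage
  profiles are, and on weak draws it degrades toward chance (reported
  honestly via its validation AUC).
* Multi-group OPLS-DA is out of scope; group score plots are produced
  pairwise or by PCA overlay.
* No vendor raw-format readers, no baseline subtraction beyond the MAD
  model, no recalibration, no survival modelling, no external-cohort
  recalibration.
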