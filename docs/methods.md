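# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
decisions that were genuinely open.

## Response labeling

A patient's visits on a drug are sorted by month since the first on-drug
visit (labels are therefore invariant to input ordering); the first visit
is the baseline.

**SRI-4 (sustained).** Responder iff there is a visit at month ≥ 3 at which
SLEDAI has dropped by ≥ 4 points from baseline and the PGA has not
meaningfully worsened, and those conditions hold at *every* later on-drug
visit. "No meaningful PGA worsening" is operationalized as an increase
< 0.3 on the 0–3 scale, the standard SRI-4 convention. When BILAG flags
are present the composite additionally requires no new BILAG A and at most
one new BILAG B per visit; because many cohort tables do not record BILAG,
the clause is evaluated only when the columns exist (and can be switched
off), and its absence is flagged on the label.

**Renal (UPCR).** Responder iff UPCR is below 500 mg/g at every visit from
some month ≥ 3 through the last on-drug visit. "Reduced" presumes an
elevated baseline; patients already below 500 at baseline who stay below
are labeled responder with a `baseline_below_threshold` flag rather than
dropped, since the sustained-control interpretation is the clinically
conservative one.

**Cohort summaries.** Continuous variables: mean ± SD per response group
and a two-sided Wilcoxon–Mann–Whitney p (exact when both groups have ≤ 25
tie-free observations, otherwise normal approximation with continuity
correction). Categorical variables: count (percentage) per level and a
two-sided Fisher exact p on the level-vs-rest 2×2 table (sum of tables at
most as probable). Variables are declared patient-level (deduplicated per
patient) or sample-level (all visits), matching how clinical tables mix
demographics with visit-varying measurements. Significance stars use the
bins <0.05, <0.005, <0.0005, <0.00005. Rows missing the tested value are
dropped per variable with the count recorded. A packaged CSV transcribes
the published characteristics table of the SPARE lupus-nephritis cohort
(categorical counts per drug and response group); an expander reconstructs
a patient/sample-level table with exactly those margins so the summary
stage can be checked against the printed percentages. Three rows of the
published table are internally inconsistent (printed count and percentage
disagree, or counts exceed the group total); they are stored as printed
and excluded from consistency checks.

## Moderated differential expression

Per gene g, log2 expression y_g follows a linear model
`y_g = Xβ_g + ε_g` with design X = intercept, non-responder indicator
(the tested coefficient; positive logFC = higher in non-responders), and
the configured covariates (default: female indicator, SLEDAI, prednisone
dose, drug dose — all continuous; race deliberately excluded by default).
Repeated samples from one patient are handled by GLS under block
equicorrelation: within a patient, Cor(ε_i, ε_j) = ρ with one consensus ρ
shared by all genes (the duplicate-correlation device). Patient is *not*
also a fixed effect — that would absorb the between-patient response
contrast.

**Consensus correlation.** OLS residuals r_g = M y_g (M the projection
onto the design's orthogonal complement) give, per gene, the within-block
cross-product sum A_g = r_gᵀ(B−I)r_g and total D_g = r_gᵀr_g (B the block
indicator). Their expectations under the equicorrelated model are linear
in ρ with coefficients computable from M and B, so each gene yields a
method-of-moments ρ_g whose moment equations account exactly for the
design projection — naive ANOVA-on-residuals estimators are biased low
because between-patient covariates absorb between-patient variance (the
estimator was verified unbiased by Monte Carlo on clean block data). The
consensus is tanh(trimmed mean(atanh ρ_g)) with 10 % trimming, clipped to
the valid range (−1/(m_max−1), 1). All-singleton blocks return ρ = 0 with
a warning.

**Whitening and fit.** Σ_b^{-1/2} for an m-sample block has the closed
form a(I − J/m) + c J/m with a = (1−ρ)^{-1/2}, c = (1−ρ+mρ)^{-1/2};
whitened X and Y are fit by OLS for all genes at once. Residual variances
s²_g carry d_g = n − p degrees of freedom.

**Empirical-Bayes moderation.** The prior σ²_g ~ s₀²·d₀/χ²_{d₀} is
estimated by moment-matching the marginal distribution of log s²_g:
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² − ψ(d₀/2) +
log(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2); ψ′ is inverted by Newton
iteration (tolerance 1e-8). d₀ above 1e6 is reported as the ∞ sentinel; in
that no-heterogeneity limit s₀² is the geometric mean of the observed
variances (so identical inputs return themselves exactly). The posterior
variance is the convex combination s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g),
the moderated t uses d₀ + d_g degrees of freedom (normal when infinite),
and `prior_df=0` switches moderation off, reproducing ordinary GLS t
statistics. Constant gene rows are flagged invalid and skipped; Bonferroni
correction multiplies by the number of valid genes with a strict < alpha
cut.

**Signatures, ratio score, GSEA.** Signatures split Bonferroni-significant
genes by logFC sign. The ratio score of a sample is mean(log2 expr over up
genes) / mean(over down genes); a non-positive down-mean raises an error
that names the positive `offset` re-anchoring option rather than silently
shifting. Cross-drug similarity uses the weighted Kolmogorov–Smirnov
running sum on a fold-change-ranked list: hits increment by
|w|^p / Σ_set |w|^p, misses decrement by 1/(N−N_set), ES is the extreme
deviation; p = 1 by default (p = 0 gives the hand-checkable unweighted
statistic), NES divides by the mean |ES| of same-sign gene-label
permutations, and the permutation p uses add-one smoothing so it lies in
(0, 1]. 1000 permutations and an explicit seed by default.

## Cell profiles

Deconvolution solves, per sample, min ‖B f − y‖ s.t. f ≥ 0 over the basis
genes (scipy NNLS) and renormalizes f to sum to 1 — a declared stand-in
for ν-SVR-based tools built on the same linear mixing model; the basis is
an input, and non-circulating populations can be excluded post-fit.
Rich/poor stratification takes patient-mean fractions, splits at the
median across patients (strictly greater = rich, ties = poor —
deterministic), while response rates are computed over samples with a
two-sided Fisher exact test, matching the mixed patient/sample phrasing of
clinical practice. Whether stratification uses patient means or individual
samples is configurable; patient means are the default.

## Single-cell stage

Cells live in an AnnData (cells × genes counts). QC statistics are all
computed on the unfiltered matrix, so the kept set is independent of rule
order: mitochondrial ("MT-") or ribosomal ("RPS"/"RPL") count share
> 25 %; library size or detected-feature count outside the 0.5–99.5
percentile band; < 200 features; Gini or Simpson diversity < 0.8. The
diversity formulas are design choices (the field uses several): Simpson is
the Gini–Simpson index 1 − Σp² and "Gini diversity" is 1 − (Gini
coefficient), both over detected genes only so sparsity does not dominate;
both thresholds are configurable because the 0.8 cut depends on these
choices. After cell filtering, genes in < 5 kept cells and all mito/ribo
genes are removed. Normalization fixes each cell's total at 1000 counts
and applies log1p; optional per-gene standardization is off by default.

Module scores bin genes into 24 equal-size bins by mean expression; each
signature gene draws 100 control genes from its bin (excluding signature
genes, with replacement when the bin is thin — logged), and
score(cell) = mean over signature genes − mean over pooled controls, so a
random gene set scores ≈ 0 by construction. Control sampling uses a
dedicated seeded RNG. Cluster markers are cluster-vs-rest two-sided
rank-sum tests per gene (exact for small tie-free clusters, asymptotic
otherwise) with mean log-expression difference and per-cluster Bonferroni
adjustment, reporting the top 10. Subcluster score summaries report, per
major cell type, the maximum of the subcluster mean scores and its argmax;
negative means are not clipped. Doublet removal, integration, graph
clustering and embeddings are deliberately out of scope — synthetic cells
carry ground-truth cluster labels.

## Druggability

Circuits are signed acyclic digraphs with ≥ 1 receptor (indegree 0),
exactly one effector (outdegree 0), every node on a receptor→effector path
and ≥ 1 annotated gene per node. Gene values are rank-scaled across
samples to (0,1) (mid-rank/(n+1)); node values average member genes.
Signals propagate in topological order:
S_r = v_r for receptors, otherwise
S_n = v_n · (1 − ∏_{activators}(1 − S_a)) · ∏_{inhibitors}(1 − S_i),
which is bounded in [0,1] and monotone in the expected directions; circuit
activity is the effector signal. Inhibition multiplies target-gene
expression (positive scale) by 0.1. Perturbed values are re-scaled against
the empirical distribution of the *unperturbed* cohort: scaling the
perturbed matrix against itself would leave within-gene ranks unchanged
and erase the perturbation, so reference-anchored ranks are the coherent
reading (a knocked-down value lands where it would insert among the
original values, strictly lower whenever original values fall in between).
A patient's response score for a target set is Σ over circuits
|activity_after − activity_before| (a per-node variant is available behind
a flag; which aggregation the original mechanistic tooling used is
ambiguous, so both exist and neither is asserted as canonical). Favorable
response = score ≥ the mean score of the scope cohort (inclusive); the
scope defaults to all patients on the drug and the reported rate is the
favorable fraction within a group (e.g. non-responders). Circuits whose
genes do not intersect the target set contribute nothing; if no circuit
depends on the targets the scores are zero with a warning.

## Nested cross-validation

Folds are built at the patient level: groups are shuffled (seeded), sorted
by size, and greedily assigned to the fold with the fewest samples of the
group's majority class (ties: fewest total, then lowest index) — so no
patient's samples ever span train and test, per-class counts stay
balanced, and the plan is deterministic given the seed. The outer loop has
5 folds; hyperparameters are tuned per outer-train by grouped 10-fold CV
repeated 5 times, selecting the combination with the highest mean inner
MCC (the inner metric is MCC because model prioritization is by MCC; inner
fold count shrinks automatically when an outer-train has fewer than 10
patients). MCC is computed from the closed-form confusion expression with
the 0-on-zero-marginal convention. The classifier zoo delegates to
scikit-learn (and xgboost when installed): eleven families mirroring
common practice, as configuration — the package's own contribution is the
fold construction, tuning loop and MCC accounting. Features default to the
top-10 signature genes by adjusted p per drug. Labels are permuted at the
patient level in null checks so grouped folds remain valid.

## Synthetic data: what it emulates, and what it does not

**Bulk cohort.** Log2 expression `baseline_g + u_{p,g} + covariate terms +
planted shift + ε`, with per-gene patient intercepts u_{p,g} ~ N(0, σ_p²)
(independent across genes — each gene's repeated measures share a patient
level, exactly the structure the per-gene mixed model assumes) and
ε ~ N(0, σ_e²). Defaults: 15 patients/arm, 3 visits at months 0/3/6, 500
genes, 20+20 planted genes per drug shifted ±1 log2 unit in non-responder
samples of the matching drug only (drug-specificity of the signatures),
σ_p = σ_e = 0.5 (intra-patient correlation 0.5). Clinical covariates
mirror the published cohort: ~90 % female; doses drawn from the published
group means/SDs (MMF ≈ 1550 ± 900 vs 2440 ± 975 mg; prednisone 5 ± 7.2 vs
10.4 ± 13.5 mg — non-responders dosed higher, so dose is genuinely
confounded with response at the strength seen in the real cohort, and the
design must adjust for it). SLEDAI/PGA/UPCR trajectories are generated so
that the SRI-4 and UPCR labelers recover the planted response labels
exactly. Not emulated: microarray probe effects, batch structure,
ancestry-linked expression, missing visits.

**Single cell.** Poisson counts with near-uniform per-gene rates
(lognormal spread σ ≈ 0.15, mito/ribo per-gene rates comparable to the
rest), ~20 000 counts/cell, 4 clusters, a 30-gene program over-expressed
(×1.5) in cluster `cl0`, and a planted low-quality fraction with ~45 %
mitochondrial share and ~150-count libraries — low-quality cells violate
several default QC rules at once while healthy cells pass the diversity
cutoffs. The near-uniform rates are a generator contract, not realism:
real scRNA-seq count distributions are far more skewed than the 0.8
Gini-evenness threshold tolerates, which is exactly why the thresholds are
configurable. Not emulated: doublets, batch/donor effects, UMI saturation,
realistic gene-abundance skew.

**Basis/mixtures.** Block-marker basis (each type owns a high-expression
marker block), Dirichlet fractions summing to 1, optional Gaussian noise
as a fraction of mean signal.

**Circuits.** A chain backbone of activations (node 0 receptor, last node
effector) guarantees acyclicity, reachability and ≥ 1 activating parent
per non-receptor node (the propagation rule yields 0 for a node with no
activators); random shortcut edges are inhibitions with the configured
probability.

All generators are pure functions of config + seed; identical reruns are
byte-identical. Passing tests on these data demonstrate the correctness
and calibration of the machinery under the stated model — not performance
on real cohorts.

## Problem sizes and numerical choices

Calibration and recovery checks run at deliberately modest sizes chosen as
representative of the cohorts the methods target: null calibration uses
100 replicates of the default cohort (15 patients/arm × 3 visits, 500
genes); planted-signature recovery uses 30 independent samples per arm
(one visit per patient — with a single visit the patient intercept is
indistinguishable from residual noise); deconvolution checks use 100
mixtures of 5 types × 60 markers; propagation oracles use 1000 random
circuits of ≤ 8 nodes; exact-test oracles enumerate all 2×2 tables with
margins ≤ 15 and all rank configurations with ≤ 8 per group; nested-CV
checks use 30 patients × 2 samples with two Gaussian classes 4σ apart.
Under a faithful null the probability that a 500-gene screen has zero
Bonferroni false positives is (1 − 0.05/m)^m ≈ e^−0.05 ≈ 0.951 per
replicate, so the zero-FP count across 100 replicates fluctuates around
95 — the expected behavior of a correctly calibrated screen, not a defect.

Other numerical choices: trigamma inversion Newton-tolerance 1e-8 with the
1e6 ∞-sentinel cap; ρ clipped inside its valid range before atanh;
rank-scale mid-ranks handle ties exactly as average ranks; fraction
renormalization guards all-zero rows; module-score bins fall back to
with-replacement sampling for thin bins (logged); Fisher tables with a
zero margin raise rather than return 1.

## Known limitations

- The consensus-ρ plug-in ignores the uncertainty of ρ̂; in very small
  cohorts the extreme tail of the moderated test inherits mild
  anticonservatism from that plug-in (negligible at the default sizes).
- NNLS deconvolution is a linear-mixture stand-in: no batch correction of
  the basis, no absolute-abundance mode, no ν-SVR robustness to unmodeled
  content.
- The ×0.1 inhibition rule and circuit propagation make no pharmacological
  claims beyond the mechanistic bookkeeping; toy circuits stand in for
  curated pathway databases.
- The QC diversity indices are one concrete reading of loosely specified
  practice; thresholds must be revisited for real data.
- Dose covariates enter the design as continuous values; categorical
  dosing schemes are not modeled.
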