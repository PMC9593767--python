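# Methods

This note documents the models, conventions and design choices behind
`neutroscope`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, what the synthetic generator does and
does not emulate, and where the genuinely open choices were made.

## Synthetic cohort generator

The generator emulates a multi-sample single-cell study of septic blood
with complete ground truth.

**Count law.** Gene counts are negative binomial, realised as a
gamma–Poisson mixture: for cell *c* with library-size factor
*L꜀* ~ Lognormal(μ = ln 2627, σ = 0.35) and type profile **p** (a
probability vector over genes), gene *g* has mean μ = L꜀·p_g and variance
μ + φμ² with one shared dispersion φ (default 0.3). A single shared
dispersion keeps the model invertible in tests; 2627 UMIs matches the
emulated cohort's mean depth.

**Cell types.** Nine major types with default mixing (neutrophils 0.55,
monocytes 0.12, CD4 T 0.10, CD8 T 0.07, B 0.05, NK 0.04, DC 0.03,
megakaryocytes 0.02, erythrocytes 0.02); per-sample composition is drawn
Dirichlet around these means (concentration 60) so fractions genuinely
vary across samples. Each type carries `markers_per_type` marker genes
up-weighted by 2^`marker_log2fc` (default 2.0) before profile
renormalization; the four neutrophil subtypes additionally carry their
own marker programs on top of the shared neutrophil panel. The first
markers of each subtype get canonical names (MMP9/HP/RGL4/FCN1 for the
immature Neu1-like subtype, FTH1/TNFAIP3/SIGLEC10/CD14 for Neu2, and so
on) so packaged signature files resolve.

**Severity and clinical structure.** Severity is generated first:
each patient draws a SOFA-like baseline uniform on 2–20 (+3 if the
patient is in shock, 40% prevalence), declining by 2 per study day
(days 1/3/5), clipped to 0–24. The circulation component is ≥2 for shock
patients (shock is defined by vasopressor need) and 0–1 otherwise.
Subtype mixing then follows severity: the Neu1-like proportion obeys a
logit link, logit p₁ = logit(0.40) + `severity_coupling`·(SOFA − 11),
with the remaining subtypes sharing the complement in a fixed 3:2:1
ratio. Generating severity before composition keeps the direction of the
planted association (immature-subtype expansion with severity) free of
circularity. Ages are uniform on 52–90 and sex is 3:1 male, matching the
emulated cohort's demographics.

**QC truth.** A damaged-cell subpopulation (default 5%) has its
mitochondrial block (13 MT- genes, baseline 4% of the library)
up-weighted 8-fold (≈25% mitochondrial share), giving the mito filter
true positives. An apoptotic subpopulation (default 20% of neutrophils)
up-weights a 12-gene apoptosis program by 2^1.5, giving the mixture
classifier a planted truth.

**Pseudobulk.** Bulk columns are exact per-sample count sums, optionally
perturbed by entrywise lognormal noise with coefficient of variation
`noise_cv` (mean-one parameterization). True fractions are realized
cell-count proportions.

**Metagene module matrix.** `simulate_module_matrix` plants a
genes × cells matrix V ≈ W·H with disjoint gene blocks per module and
per-cell usages drawn Dirichlet around per-sample means; one module's
per-sample mean is linear in severity (slope 0.12, residual sd 0.09,
giving a planted usage–severity correlation near 0.8). The Dirichlet
concentration defaults to 1.5: usages are sparse, most cells are
dominated by one module, and the planted rank is therefore identifiable
by consensus clustering of dominant-module assignments — with near-even
mixing the notion of a "module structure of rank K" would be vacuous.

**What the generator does not emulate** (and what passing tests
therefore do not show about real data): batch effects and the need for
integration across samples, doublets and ambient RNA, within-patient
longitudinal correlation beyond the deterministic severity trajectory,
realistic gene–gene correlation inside programs (markers are
conditionally independent given the profile), and the continuous
maturation gradient of real neutrophils — planted subtypes are discrete,
so clustering recovery here is an upper bound on what continuous biology
allows.

## QC and preprocessing

Cells are removed when detected features exceed 2500 or fall below 200
or the mitochondrial percentage exceeds 10; the thresholds are strict
inequalities for removal, so boundary cells (exactly 200, 2500, 10%) are
kept, and a cell with zero UMIs has mitochondrial percentage 0 by
convention. Mitochondrial genes are matched by a case-insensitive `MT-`
prefix (configurable regex). Normalization is fixed to library-size
scaling to 10⁴ plus log1p. HVGs are ranked by the residual of log
variance against a running-median trend over 20 mean-expression bins;
constant genes rank last and ties break lexicographically by gene id, so
the ranking is fully deterministic.

## Two-step stability clustering

Clustering is Leiden (RB-configuration modularity, 2 iterations) on an
unweighted undirected kNN graph (k = 15, Euclidean) over the top 30 PCs
of the z-scaled (clipped at ±10) HVG matrix. The first pass runs at
resolution 0.15; the neutrophil compartment — which may span several
first-pass clusters when subtypes separate strongly — is called by a
marker panel: clusters whose mean panel expression clears the midpoint
of the cluster-score range. The panel is user-supplied configuration
(cell-type naming is deliberately outside the clustering engine); for
synthetic runs it is the generator's planted neutrophil panel.

The second pass re-selects HVGs and PCs within the compartment and scans
resolutions with the subsample procedure: per resolution, the full data
are clustered once; each of 20 iterations draws ⌊0.9·n⌋ cells without
replacement (iteration *i* reuses seed `base + i`, so subsamples are
shared across resolutions), re-clusters the subsample, and computes the
ARI between the subsample labels and the reference labels restricted to
the same cells. Restriction-to-shared-cells (rather than
subsample-vs-subsample pairs) is the more literal reading of comparing
"original" and "subsampled" solutions; mean (not median) ARI summarizes
the 20 iterations. The selected resolution is r_k for the smallest k
with mean ARI dropping by more than δ = 0.05 from r_k to r_{k+1} — a
raw first-difference sign test would be noise-dominated at 20
iterations — and the largest scanned resolution when no such drop
exists (on cleanly separated data the curve never declines, and every
resolution yields the same stable partition).

The ARI is the Hubert–Arabie adjusted form; when both partitions are
trivial (the denominator vanishes) it is 1 by convention. Markers are
one-vs-rest Wilcoxon rank-sum tests (exact for small tie-free groups,
tie-corrected asymptotic otherwise), log2 fold changes on expm1-means
with pseudocount 1, Benjamini–Hochberg correction across the whole
table, and default filters log2FC ≥ 0.25, expressed in ≥10% of either
group.

## Signature scores and the apoptosis mixture

Mean-expression scores average normalized expression over present
signature genes (absent genes are dropped with a warning; an all-absent
signature is an error). The aging score z-scores each gene across all
cells, drops constant genes, and averages weight·z with weights in
{+1, −1}; it is the plain mean over genes (no weight-sum
normalization). Gene lists are configuration (YAML), since the emulated
study's exact per-function lists come from ontology databases; packaged
examples cover apoptosis, maturation, azurophil, interferon response and
a ±-weighted aging signature.

The apoptosis classifier fits a two-component univariate Gaussian
mixture by EM: five starts (a median split first, random
responsibilities after), variances floored at 10⁻⁶·var(x) to prevent
collapse, convergence when the log-likelihood gain falls below 10⁻⁸,
components canonicalized so index 0 has the lower mean. The higher-mean
component is apoptotic; cells are assigned by posterior with exact ties
(posterior 0.5) going to the non-apoptotic side — the maximum-posterior
rule, not a higher-confidence cutoff. On unimodal input the two
components nearly coincide and the downstream split is near-chance;
this is documented behaviour, not an error.

## Consensus NMF

The module input is the severity-associated subtype's log-normalized
expression restricted to its top 500 HVGs (genes × cells, non-negative
by construction). Factorization minimizes ‖V − WH‖²_F by multiplicative
updates from uniform-random starts, stopping at relative RSS change
below 10⁻⁶ (10⁻⁵ with a 300-iteration cap inside the consensus loop,
where only dominant-module assignments matter); W columns are rescaled
to unit L1 with compensating H scaling, leaving WH unchanged. Frobenius
updates were chosen over divergence-based ones for numeric robustness.
Per rank, 30 runs (seeds `base + run`) assign each cell to its argmax
metagene; the consensus matrix C holds co-assignment frequencies, and
the reported metrics are the cophenetic correlation of 1 − C against its
average-linkage cophenetic distances, dispersion mean 4(C − ½)², the
mean silhouette of the consensus tree cut at the candidate rank under
distance 1 − C, and the best-run RSS. The default selection is the
cophenetic argmax with ties broken by dispersion then smaller rank; the
full table is always emitted so a collective judgement stays auditable.
Module letters follow descending total usage for reporting.

## Deconvolution

The signature matrix is the union of the top 50 markers per labeled type
(ranked by log2FC), with entries the per-type mean of expm1(normalized
expression); an ill-conditioned signature (condition number > 10⁶)
warns. Bulk samples are solved per column by NNLS on the shared genes
(≥50% coverage required) after scaling each bulk column to unit total;
the signature keeps its relative column scale up to one global factor —
rescaling signature columns individually would be absorbed into the
coefficients and bias the recovered fractions, breaking exact recovery
of noiseless mixtures, which is this module's defining invariant.
Solutions are renormalized to fractions summing to 1. Log-scale bulk
input (all values < 50) is detected and expm1-reversed with a warning.
NNLS, not the ν-SVR of the original CIBERSORT, is the reference solver:
deconvolution is a means here, not a contribution.

## Statistics

Pearson correlation uses the exact t-based p-value on n − 2 df; Welch
(Satterthwaite df) for condition comparisons, pooled-variance Student
for day-wise comparisons; Bonferroni–Holm step-down for families of
tests. AUC is the Mann–Whitney U-statistic with half-credit ties, so
AUC(s) + AUC(−s) = 1 exactly; an optional percentile bootstrap CI is
seeded. The logistic model is fitted by IRLS to gradient norm < 10⁻⁸
with Wald standard errors from the inverse information matrix;
continuous covariates are z-scored and the interaction column is the
product of the standardized fractions (centering decorrelates the main
effects without changing the fit). Non-convergence and separation raise
errors rather than returning silent estimates. Stratified effect curves
evaluate predicted shock probability along a neutrophil grid at the
10/50/90% monocyte quantiles, with adjustment covariates at reference
values. Repeated samples from the same patient are treated as
independent in the day-wise tests — a deliberate replication of the
emulated workflow and a documented limitation, not an endorsement.

## Pipeline, determinism and problem sizes

One global seed fans out to per-stage seeds by fixed offsets
(simulate +0, first pass +1000, scan +2000, GMM +3000, NMF +4000,
pseudobulk +5000, clinical +6000), so any stage reruns in isolation and
two identical runs agree bit-for-bit. Every written artifact carries a
`#`-comment header with version, seed and configuration hash.

Default parameters are the emulated study's printed values where they
exist: QC 200/2500/10%, first-pass resolution 0.15, 90% subsamples with
20 iterations, and a resolution grid bracketing the second-step choice
of 0.2. The full-size default configuration (32 samples × 4000 cells) is
a desk-scale stand-in for the ~291k-cell atlas; the packaged fixture
(12 samples × 450 cells, 1200 genes, 4-point resolution grid, 8 scan
iterations, 10 NMF consensus runs) is the package's own choice of a
configuration that exercises every stage in about a minute while keeping
all planted effects at their default strengths. Test problem sizes
(e.g. ~8000 neutrophils for subtype recovery, 500 × 2000 for module
recovery, n = 5000 for mixture and logistic recovery) are likewise the
package's validation scales.

## Known limitations

- Planted subtypes are discrete and conditionally independent given
  their profiles; real neutrophil states are continuous and correlated,
  so recovery metrics here bound the idealized case.
- The marker-panel compartment call assumes a clear bimodal gap between
  panel-positive and panel-negative clusters; heavily mixed clusters
  would need proper reference-based annotation, which is out of scope.
- Deconvolution fractions are RNA-content-weighted whenever per-cell
  RNA content differs systematically between types; the generator draws
  library sizes identically across types, so this bias is invisible
  here and must be kept in mind on real bulk data.
- No batch correction, doublet handling, mixed-effects modelling of
  repeated measures, or enrichment analysis.
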