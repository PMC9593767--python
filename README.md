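# neutroscope

Stability-guided discovery of neutrophil subtypes, metagene modules, and
their association with disease severity in sepsis, from single-cell
transcriptomes — plus the signature-based deconvolution needed to score
those subtypes in bulk whole-blood cohorts.

## The scientific problem

Neutrophils dominate the nucleated cells of septic blood (>50%) yet are
heterogeneous: an immature subtype expands in the acute phase and tracks
shock severity. Finding that subtype reproducibly requires more than one
pass of graph clustering — the neutrophil compartment must first be
isolated from the whole-blood atlas and then re-clustered at a resolution
chosen for *stability*, not convenience. `neutroscope` implements that
workflow end to end:

1. **QC** — cells with >2500 or <200 detected genes, or >10%
   mitochondrial UMIs, are removed (boundaries kept); library-size
   normalization `x → ln(1 + 10⁴·c/total)`; HVG selection by a
   running-median dispersion residual.
2. **Two-step stability clustering** — Leiden community detection on a
   kNN graph (k=15) over the top 30 PCs. Stability at each candidate
   resolution *r* is the adjusted Rand index
   ARI = (Σᵢⱼ C(nᵢⱼ,2) − E)/(½(Σᵢ C(aᵢ,2)+Σⱼ C(bⱼ,2)) − E)
   between the full-data partition and partitions of twenty 90%
   subsamples; the selected resolution is the highest one before the mean
   ARI declines by more than δ = 0.05.
3. **Functional scoring** — per-cell mean-expression signatures and a
   ±1-weighted z-score aging signature; a two-component 1-D Gaussian
   mixture (EM) on the apoptosis score labels apoptotic cells by
   posterior, the higher-mean component being apoptotic.
4. **Metagene modules** — multiplicative-update NMF (V ≈ WH, Frobenius)
   of the severity-associated subtype's expression; the rank is chosen by
   consensus over 30 random restarts (cophenetic coefficient, dispersion,
   silhouette, RSS); per-cell module usage = column-normalized H.
5. **Deconvolution** — a marker-gene signature matrix of per-type mean
   linear expression, fitted to bulk samples by non-negative least
   squares with fractions renormalized to 1 (a constrained-regression
   reading of CIBERSORT-style deconvolution).
6. **Association statistics** — Pearson/Welch/Student tests with
   Bonferroni–Holm correction, shock AUC as the Mann–Whitney U-statistic,
   and an IRLS logistic model `shock ~ neu + mono + neu×mono + age + sex`
   on standardized covariates.

Because the patient-level data behind the original cohort are controlled,
the package ships a **synthetic cohort generator** that reproduces the
study's statistical structure — 9 major cell types dominated by
neutrophils, 4 planted neutrophil subtypes (an MMP9/HP/RGL4-style
immature subtype among them), negative-binomial counts with lognormal
library sizes, per-sample SOFA-like severity coupled to the immature
subtype's fraction, and a shock model with a neutrophil × monocyte
interaction — with complete ground truth, so every stage is verifiable.

## Worked example

```python
import neutroscope as ns

config = ns.fixture_config(seed=1)      # desk-scale synthetic cohort
report = ns.run_pipeline(config, out_dir="out")
print(report.to_json())
```

Key excerpts of the report this prints (seed 1):

```
"qc":        {"cells_in": 5400, "cells_kept": 5153, ...}
"subtypes":  {"selected_resolution": 0.6, "n_subtypes": 4,
              "ari_vs_truth": 0.9954, ...}
"scoring":   {"gmm_means": [1.7421, 2.7399], "apoptotic_fraction": 0.1786,
              "apoptotic_accuracy_vs_truth": 0.9688, ...}
"deconv":    {"mean_rmse": 0.0398, "r_neu1_fraction": 0.9736, ...}
"stats":     {"auc_neu1_fraction_shock": 0.7222,
              "interaction_coef": -0.6637, ...}
```

Reading: QC removed 247 of 5400 cells; the stability scan admitted the
highest scanned resolution and recovered the four planted neutrophil
subtypes almost exactly (ARI 0.995 against truth); the apoptosis mixture
called 17.9% of neutrophils apoptotic (96.9% agreement with the planted
labels); pseudobulk deconvolution recovered the immature-subtype fraction
across samples at r = 0.97; and that fraction discriminated shock with
AUC 0.72, while the clinical logistic model recovered the planted
negative neutrophil × monocyte interaction.

The same stages are available from the shell:

```bash
neutroscope run-all --out out --seed 1 --fixture
neutroscope simulate --out sim --seed 1
neutroscope qc --in sim --out qcd
neutroscope cluster --in qcd --out clu --scan 0.05,0.1,0.2,0.4 --iters 20 --seed 1
```

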