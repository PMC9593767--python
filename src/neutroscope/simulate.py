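"""Synthetic sepsis peripheral-blood cohort generator.

Emulates the statistical structure of a multi-sample single-cell study of
sepsis: a whole-blood atlas dominated by neutrophils (>50%), four planted
neutrophil subtypes with marker programs, per-sample SOFA-like severity
coupled to the immature (Neu1-like) subtype fraction, pseudobulk mixtures
for deconvolution, and a clinical table whose shock outcome follows a
logistic model with a neutrophil x monocyte interaction.

Every stochastic quantity is drawn from a single seeded generator, so the
same configuration and seed reproduce counts bit-identically, and the full
ground truth (cell types, subtypes, marker assignments, per-sample
fractions, severity, apoptotic flags) is returned alongside the data for
parameter-recovery testing.

Counts follow a negative binomial law: for cell c with library-size factor
L_c (lognormal) and type profile p (a probability vector over genes), gene
g has mean mu = L_c * p_g and variance mu + phi * mu^2 with a single shared
dispersion phi, realised as a gamma-Poisson mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ConfigurationError",
    "ShockModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_atlas",
    "simulate_pseudobulk",
    "simulate_clinical_table",
    "simulate_module_matrix",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


MAJOR_CELL_TYPES = (
    "Neutrophil",
    "Monocyte",
    "CD4_T",
    "CD8_T",
    "B",
    "NK",
    "DC",
    "Megakaryocyte",
    "Erythrocyte",
)

#: default mixing proportions; neutrophils dominate as in septic blood
DEFAULT_MAJOR_PROPORTIONS = (0.55, 0.12, 0.10, 0.07, 0.05, 0.04, 0.03, 0.02, 0.02)

#: the 13 protein-coding human mitochondrial genes
MT_GENE_NAMES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: flavour names for the first markers of each neutrophil subtype
SUBTYPE_MARKER_NAMES = {
    "Neu1": ("MMP9", "HP", "RGL4", "FCN1"),
    "Neu2": ("FTH1", "TNFAIP3", "SIGLEC10", "CD14"),
    "Neu3": ("MPO", "ELANE", "DEFA3", "AZU1"),
    "Neu4": ("FCGR3B", "CXCR2", "SELL", "IFIT1"),
}

#: planted per-cell apoptosis program (orthogonal to subtype identity)
APOPTOSIS_GENE_NAMES = (
    "CASP3", "CASP8", "BAX", "BAK1", "FAS", "TP53", "PMAIP1", "BBC3",
    "CYCS", "APAF1", "DIABLO", "CASP9",
)


@dataclass
class ShockModel:
    """Logistic coefficients for the shock outcome on standardized covariates.

    logit P(shock) = intercept + beta_neu * z_neu + beta_mono * z_mono
                     + beta_interaction * z_neu * z_mono
                     + beta_age * z_age + beta_sex * sex
    """

    intercept: float = -0.5
    beta_neu: float = 0.8
    beta_mono: float = -0.5
    beta_interaction: float = -0.6
    beta_age: float = 0.3
    beta_sex: float = 0.2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.beta_neu, self.beta_mono,
             self.beta_interaction, self.beta_age, self.beta_sex]
        )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the target study design: 32 samples from 12 patients
    over days 1/3/5, >50% neutrophils across 9 major cell types, 4
    neutrophil subtypes, a mean library size of ~2627 UMIs, ages 52-90 and
    a 3:1 male:female cohort.  `n_cells_per_sample` and `n_genes` are
    desk-scale stand-ins for the full-depth atlas.
    """

    n_samples: int = 32
    n_cells_per_sample: int = 4000
    n_genes: int = 2000
    n_mito_genes: int = 13
    major_type_proportions: tuple = DEFAULT_MAJOR_PROPORTIONS
    n_neutrophil_subtypes: int = 4
    markers_per_type: int = 20
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    libsize_log_mean: float = math.log(2627.0)
    libsize_log_sd: float = 0.35
    mito_baseline_share: float = 0.04
    damaged_cell_fraction: float = 0.05
    damaged_mito_multiplier: float = 8.0
    apoptotic_fraction: float = 0.20
    apoptosis_log2fc: float = 1.5
    severity_coupling: float = 0.25
    shock_model: ShockModel = field(default_factory=ShockModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_samples", "n_cells_per_sample", "n_genes",
                     "n_mito_genes", "n_neutrophil_subtypes", "markers_per_type"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_mito_genes >= self.n_genes:
            raise ConfigurationError("n_mito_genes must be smaller than n_genes")
        p = np.asarray(self.major_type_proportions, dtype=float)
        if p.ndim != 1 or len(p) != len(MAJOR_CELL_TYPES):
            raise ConfigurationError(
                f"major_type_proportions must have {len(MAJOR_CELL_TYPES)} entries"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                "major_type_proportions must be non-negative and sum to 1"
            )
        for name in ("marker_log2fc", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("damaged_cell_fraction", "apoptotic_fraction"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")

    @property
    def subtype_names(self) -> list:
        return [f"Neu{i + 1}" for i in range(self.n_neutrophil_subtypes)]


@dataclass
class GroundTruth:
    """Planted truth channel for parameter-recovery tests."""

    cell_type: pd.Series  # per cell, major type
    neutrophil_subtype: pd.Series  # per cell; NaN outside neutrophils
    apoptotic: pd.Series  # per cell boolean
    damaged: pd.Series  # per cell boolean (elevated mito share)
    true_fractions: pd.DataFrame  # sample x deconvolution-type realized fractions
    samples: pd.DataFrame  # per-sample clinical covariates
    marker_gene_assignment: dict  # gene -> (type-or-subtype, planted log2fc)
    signature_genes: dict  # program name -> gene list

    def validate(self) -> None:
        sums = self.true_fractions.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)
        shock = self.samples["shock"].to_numpy(bool)
        assert (self.samples.loc[shock, "sofa_circulation"] >= 2).all()


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _build_gene_panel(config: SimulationConfig, rng: np.random.Generator):
    """Gene identifiers, baseline weights and marker assignments.

    Returns (gene_ids, baseline weight vector, marker index dict
    type->array, apoptosis gene index array, mito index array).
    """
    n = config.n_genes
    n_mito = config.n_mito_genes
    gene_ids = [f"GENE{i:05d}" for i in range(n)]
    mito_idx = np.arange(n_mito)
    for i in range(n_mito):
        gene_ids[i] = MT_GENE_NAMES[i] if i < len(MT_GENE_NAMES) else f"MT-EXT{i}"

    pool = list(range(n_mito, n))
    rng.shuffle(pool)
    cursor = 0

    def take(k):
        nonlocal cursor
        if cursor + k > len(pool):
            raise ConfigurationError(
                "n_genes too small for the requested markers_per_type"
            )
        out = np.array(pool[cursor:cursor + k])
        cursor += k
        return out

    marker_idx = {}
    groups = list(MAJOR_CELL_TYPES) + [f"Neu{i+1}" for i in range(config.n_neutrophil_subtypes)]
    for grp in groups:
        idx = take(config.markers_per_type)
        marker_idx[grp] = idx
        for j, name in enumerate(SUBTYPE_MARKER_NAMES.get(grp, ())):
            if j < len(idx):
                gene_ids[idx[j]] = name
    apo_idx = take(min(len(APOPTOSIS_GENE_NAMES), config.markers_per_type))
    for j, name in enumerate(APOPTOSIS_GENE_NAMES[: len(apo_idx)]):
        gene_ids[apo_idx[j]] = name

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    # fix the mitochondrial block to a target share of the library
    non_mito_sum = base[n_mito:].sum()
    share = config.mito_baseline_share
    base[:n_mito] = share / (1.0 - share) * non_mito_sum / n_mito
    return gene_ids, base, marker_idx, apo_idx, mito_idx


def _type_profiles(config, base, marker_idx):
    """Unnormalized expression weight vector per (sub)type label."""
    fc = 2.0 ** config.marker_log2fc
    profiles = {}
    for t in MAJOR_CELL_TYPES:
        w = base.copy()
        w[marker_idx[t]] *= fc
        profiles[t] = w
    for s in [f"Neu{i+1}" for i in range(config.n_neutrophil_subtypes)]:
        w = profiles["Neutrophil"].copy()
        w[marker_idx[s]] *= fc
        profiles[s] = w
    return profiles


def _sample_clinical(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample severity, shock, circulation SOFA and demographics.

    Samples are grouped into patients of up to three study days (1/3/5);
    severity starts at a uniform 2-20 baseline (plus a shock bonus) and
    declines along the patient's trajectory, mirroring clinical recovery.
    """
    n = config.n_samples
    n_patients = (n + 2) // 3
    base_sev = rng.integers(2, 21, size=n_patients)
    shock_pat = rng.random(n_patients) < 0.4
    age = rng.integers(52, 91, size=n_patients)
    sex = (rng.random(n_patients) < 0.75).astype(int)  # 1 = male

    rows = []
    for s in range(n):
        pat = s // 3
        day_index = s % 3
        day = (1, 3, 5)[day_index]
        sev = int(np.clip(base_sev[pat] + 3 * shock_pat[pat] - 2 * day_index, 0, 24))
        if shock_pat[pat]:
            circ = 2 + int(rng.binomial(2, min(1.0, sev / 24.0)))
        else:
            circ = int(rng.random() < 0.3 * sev / 20.0)
        rows.append(
            dict(sample=f"S{s:03d}", patient=f"P{pat:02d}", day=day,
                 severity=sev, sofa_circulation=circ,
                 shock=bool(shock_pat[pat]), age=int(age[pat]), sex=int(sex[pat]))
        )
    return pd.DataFrame(rows).set_index("sample")


def _subtype_proportions(config: SimulationConfig, severity: np.ndarray) -> np.ndarray:
    """Neutrophil subtype mixing per sample.

    The Neu1-like (immature) subtype proportion follows a logit link in
    sample severity with slope `severity_coupling`; the remaining subtypes
    share the complement in fixed ratio.
    """
    k = config.n_neutrophil_subtypes
    base = np.full(k, 1.0 / k)
    if k >= 4:
        base = np.array([0.40, 0.30, 0.20, 0.10] + [0.0] * (k - 4))
        if k > 4:
            base[4:] = 0.05 / (k - 4)
            base = base / base.sum()
    centred = np.asarray(severity, dtype=float) - 11.0
    p1 = _expit(_logit(base[0]) + config.severity_coupling * centred)
    props = np.empty((len(p1), k))
    props[:, 0] = p1
    rest = base[1:] / base[1:].sum()
    props[:, 1:] = (1.0 - p1)[:, None] * rest[None, :]
    return props


def _draw_counts(rng, profile, libsizes, phi):
    """Gamma-Poisson draw: NB with mean L*p and variance mu + phi*mu^2."""
    mu = np.outer(libsizes, profile)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_atlas(config: SimulationConfig):
    """Generate the synthetic single-cell atlas.

    Returns
    -------
    adata : AnnData (cells x genes, sparse integer counts)
        with per-cell metadata in ``.obs`` (sample, true type/subtype,
        damaged and apoptotic flags) and gene metadata in ``.var``.
    samples : DataFrame — per-sample clinical covariates.
    truth : GroundTruth — full planted truth channel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids, base, marker_idx, apo_idx, mito_idx = _build_gene_panel(config, rng)
    profiles = _type_profiles(config, base, marker_idx)
    samples = _sample_clinical(config, rng)
    sub_props = _subtype_proportions(config, samples["severity"].to_numpy())

    major_p = np.asarray(config.major_type_proportions, dtype=float)
    # mild per-sample composition variation so fractions differ across samples
    alpha = major_p * 60.0
    subtypes = config.subtype_names
    deconv_types = [t for t in MAJOR_CELL_TYPES if t != "Neutrophil"] + subtypes

    blocks, obs_rows = [], []
    frac_rows = np.zeros((config.n_samples, len(deconv_types)))
    apo_fc = 2.0 ** config.apoptosis_log2fc

    for s, (sample_id, row) in enumerate(samples.iterrows()):
        sample_props = rng.dirichlet(alpha)
        type_counts = rng.multinomial(config.n_cells_per_sample, sample_props)
        labels, sublabels = [], []
        for t, nt in zip(MAJOR_CELL_TYPES, type_counts):
            if t == "Neutrophil":
                sub_counts = rng.multinomial(nt, sub_props[s])
                for st, ns in zip(subtypes, sub_counts):
                    labels += [t] * ns
                    sublabels += [st] * ns
            else:
                labels += [t] * nt
                sublabels += [None] * nt
        n_cells = len(labels)
        labels = np.array(labels)
        sublabels = np.array(sublabels, dtype=object)
        damaged = rng.random(n_cells) < config.damaged_cell_fraction
        is_neu = labels == "Neutrophil"
        apoptotic = np.zeros(n_cells, dtype=bool)
        apoptotic[is_neu] = rng.random(is_neu.sum()) < config.apoptotic_fraction
        libsizes = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)

        counts = np.zeros((n_cells, config.n_genes), dtype=np.int32)
        group_key = np.where(is_neu, sublabels.astype(str), labels)
        for key in np.unique(group_key):
            for dmg in (False, True):
                for apo in (False, True):
                    mask = (group_key == key) & (damaged == dmg) & (apoptotic == apo)
                    if not mask.any():
                        continue
                    w = profiles[key].copy()
                    if dmg:
                        w[mito_idx] *= config.damaged_mito_multiplier
                    if apo:
                        w[apo_idx] *= apo_fc
                    p = w / w.sum()
                    counts[mask] = _draw_counts(rng, p, libsizes[mask], config.nb_dispersion)

        blocks.append(sp.csr_matrix(counts))
        for i in range(n_cells):
            obs_rows.append((f"{sample_id}-C{i:05d}", sample_id, labels[i],
                             sublabels[i], bool(damaged[i]), bool(apoptotic[i])))
        keys, cnts = np.unique(group_key, return_counts=True)
        for key, c in zip(keys, cnts):
            frac_rows[s, deconv_types.index(key)] = c / n_cells

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "sample", "cell_type", "neutrophil_subtype",
                 "damaged", "apoptotic"],
    ).set_index("barcode")
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    marker_assignment = {}
    var["marker_of"] = ""
    for grp, idx in marker_idx.items():
        for i in idx:
            var.iloc[i, var.columns.get_loc("marker_of")] = grp
            marker_assignment[gene_ids[i]] = (grp, config.marker_log2fc)

    signature_genes = {
        "apoptosis": [gene_ids[i] for i in apo_idx],
        "maturation": [gene_ids[i] for i in marker_idx.get("Neu4", [])],
        "azurophil": [gene_ids[i] for i in marker_idx.get("Neu3", [])],
        "ifn_response": [gene_ids[i] for i in marker_idx.get("Neu2", [])],
        "gelatinase": [gene_ids[i] for i in marker_idx.get("Neu1", [])],
    }

    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["simulation"] = {"seed": config.seed, "n_genes": config.n_genes}
    truth = GroundTruth(
        cell_type=obs["cell_type"],
        neutrophil_subtype=obs["neutrophil_subtype"],
        apoptotic=obs["apoptotic"],
        damaged=obs["damaged"],
        true_fractions=pd.DataFrame(frac_rows, index=samples.index, columns=deconv_types),
        samples=samples,
        marker_gene_assignment=marker_assignment,
        signature_genes=signature_genes,
    )
    truth.validate()
    return adata, samples, truth


def simulate_pseudobulk(counts, cell_labels, sample_ids, noise_cv: float = 0.0,
                        seed: int = 0, samples=None):
    """Aggregate single-cell counts into per-sample bulk profiles.

    Parameters
    ----------
    counts : AnnData or sparse/ndarray (cells x genes)
    cell_labels : per-cell type labels (used for the true-fraction table)
    sample_ids : per-cell sample identifiers
    noise_cv : coefficient of variation of multiplicative lognormal noise
        applied entrywise to the bulk matrix (0 = exact column sums).
    samples : optional explicit sample ordering; unknown ids raise.

    Returns
    -------
    bulk : DataFrame genes x samples
    fractions : DataFrame samples x types of realized cell-count proportions
    """
    if hasattr(counts, "X"):
        gene_index = counts.var_names
        X = counts.X
    else:
        X = counts
        gene_index = pd.RangeIndex(X.shape[1])
    X = sp.csr_matrix(X)
    sample_ids = np.asarray(sample_ids)
    cell_labels = np.asarray(cell_labels)
    if len(sample_ids) != X.shape[0] or len(cell_labels) != X.shape[0]:
        raise ValueError("cell_labels and sample_ids must cover all cells")
    uniq = pd.unique(sample_ids) if samples is None else list(samples)
    unknown = set(sample_ids) - set(uniq)
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(unknown)}")

    types = pd.unique(cell_labels)
    bulk = np.zeros((X.shape[1], len(uniq)))
    fracs = np.zeros((len(uniq), len(types)))
    for j, sid in enumerate(uniq):
        mask = sample_ids == sid
        if not mask.any():
            continue
        bulk[:, j] = np.asarray(X[mask].sum(axis=0)).ravel()
        lab, cnt = np.unique(cell_labels[mask], return_counts=True)
        for l, c in zip(lab, cnt):
            fracs[j, list(types).index(l)] = c / mask.sum()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = math.log(1.0 + noise_cv ** 2)
        noise = rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=bulk.shape)
        bulk = bulk * noise
    bulk_df = pd.DataFrame(bulk, index=gene_index, columns=list(uniq))
    frac_df = pd.DataFrame(fracs, index=list(uniq), columns=list(types))
    return bulk_df, frac_df


def simulate_clinical_table(config: SimulationConfig, n_patients: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic critical-care clinical table with a planted shock model.

    Differential fractions (neutrophil/monocyte/band, percent of the white
    count, summing below 100) come from a Dirichlet model; shock is drawn
    Bernoulli from `config.shock_model` applied to standardized covariates
    including the neutrophil x monocyte product term.
    """
    if n_patients < 50:
        raise ConfigurationError("n_patients must be at least 50")
    rng = np.random.default_rng(seed)
    fr = rng.dirichlet([55.0, 8.0, 4.0, 33.0], size=n_patients) * 100.0
    neu, mono, band = fr[:, 0], fr[:, 1], fr[:, 2]
    age = rng.uniform(52, 90, size=n_patients)
    sex = (rng.random(n_patients) < 0.75).astype(int)

    def z(v):
        return (v - v.mean()) / v.std()

    b = config.shock_model
    lin = (b.intercept + b.beta_neu * z(neu) + b.beta_mono * z(mono)
           + b.beta_interaction * z(neu) * z(mono) + b.beta_age * z(age)
           + b.beta_sex * sex)
    shock = rng.random(n_patients) < _expit(lin)
    circ = np.where(shock, 2 + rng.binomial(2, 0.5, n_patients),
                    rng.binomial(1, 0.3, n_patients))
    return pd.DataFrame({
        "neutrophil_pct": neu, "monocyte_pct": mono, "band_pct": band,
        "age": age, "sex": sex, "sofa_circulation": circ,
        "shock": shock.astype(int),
    })


def simulate_module_matrix(n_genes: int = 500, n_cells: int = 2000,
                           n_modules: int = 4, n_samples: int = 32,
                           coupled_module: int = 1, usage_slope: float = 0.12,
                           usage_noise_sd: float = 0.09,
                           concentration: float = 1.5,
                           noise_cv: float = 0.1, seed: int = 0):
    """Planted metagene-module expression matrix for factorization tests.

    Builds V ~= W_true @ H_true with disjoint gene blocks per module,
    per-cell module usages drawn Dirichlet around per-sample means, and the
    coupled module's per-sample mean usage linear in a SOFA-like severity
    score (slope and residual noise chosen so the planted usage-severity
    correlation is ~0.8 at the defaults). The default concentration (1.5)
    keeps per-cell usage sparse — most cells are dominated by a single
    module — which is what makes the planted rank identifiable by
    consensus clustering of dominant-module assignments.

    Returns a dict with V (genes x cells), W_true, usage_true (cells x
    modules), sample_ids, severity (per sample).
    """
    rng = np.random.default_rng(seed)
    genes_per = n_genes // n_modules
    W = np.full((n_genes, n_modules), 0.01)
    for k in range(n_modules):
        block = slice(k * genes_per, (k + 1) * genes_per)
        W[block, k] = rng.lognormal(0.0, 0.5, genes_per) + 1.0
    W /= W.sum(axis=0, keepdims=True)

    severity = rng.integers(0, 25, size=n_samples).astype(float)
    z_sev = (severity - severity.mean()) / severity.std()
    base = np.full(n_modules, 1.0 / n_modules)
    mean_coupled = np.clip(base[coupled_module] + usage_slope * z_sev
                           + rng.normal(0, usage_noise_sd, n_samples), 0.05, 0.9)

    sample_ids = np.repeat([f"S{i:03d}" for i in range(n_samples)],
                           int(np.ceil(n_cells / n_samples)))[:n_cells]
    usage = np.empty((n_cells, n_modules))
    for i, sid in enumerate(pd.unique(sample_ids)):
        mask = sample_ids == sid
        m = np.full(n_modules, (1.0 - mean_coupled[i]) / (n_modules - 1))
        m[coupled_module] = mean_coupled[i]
        usage[mask] = rng.dirichlet(m * concentration, size=mask.sum())

    scale = rng.lognormal(math.log(200.0), 0.3, n_cells)
    V = W @ (usage * scale[:, None]).T
    if noise_cv > 0:
        s2 = math.log(1.0 + noise_cv ** 2)
        V = V * rng.lognormal(-0.5 * s2, math.sqrt(s2), size=V.shape)
    return {
        "V": V, "W_true": W, "usage_true": usage,
        "sample_ids": sample_ids, "severity": pd.Series(severity, index=pd.unique(sample_ids)),
    }
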