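"""Synthetic family cohort with correlated cardiometabolic traits, planted
transcript-trait effects, batch/cell-count structure, and Ct censoring.

The generator is the test-bed for the whole pipeline: real whole-blood
cohort data of this kind are access-controlled, so every downstream stage
is exercised on cohorts whose ground truth is known by construction.

What is emulated
----------------
* Family structure: trio / nuclear-4 / three-generation-6 families; a
  polygenic component with covariance sigma_g2 * A (A the additive
  relationship matrix) enters both the traits and the expression values,
  so relatives are correlated the way pedigree mixed models assume.
* Six cardiometabolic traits (BMI, HDL-C, TG, glucose, SBP, DBP) drawn at
  realistic means/SDs for an untreated middle-aged cohort, with a
  configurable cross-trait correlation matrix.
* mRNA log2 intensities: baseline + age/sex/batch effects + latent
  differential-cell-count loadings + planted trait effects + polygenic
  term + iid noise.
* miRNA abundance on the qPCR Ct scale (higher Ct = lower expression) with
  deterministic censoring at the detection limit: latent Ct values at or
  above the threshold are recorded as missing (non-detected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord, RelationshipMatrix, additive_relationship

__all__ = [
    "TRAITS",
    "TRAIT_MEANS",
    "TRAIT_SDS",
    "default_trait_correlation",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_pedigree",
    "generate_cohort",
    "censor_ct",
]

TRAITS = ["BMI", "HDL", "TG", "GLU", "SBP", "DBP"]

# Untreated middle-aged cohort scales: kg/m2, mg/dL (HDL, TG, glucose), mm Hg.
TRAIT_MEANS = {"BMI": 26.9, "HDL": 62.0, "TG": 104.0,
               "GLU": 95.0, "SBP": 117.0, "DBP": 74.0}
TRAIT_SDS = {"BMI": 5.0, "HDL": 18.0, "TG": 67.0,
             "GLU": 13.0, "SBP": 15.0, "DBP": 10.0}


def default_trait_correlation() -> pd.DataFrame:
    """Plausible cross-trait correlations: adiposity raises TG/BP/glucose,
    lowers HDL; HDL and TG strongly inverse; SBP-DBP strongly positive."""
    c = np.array([
        #  BMI    HDL    TG     GLU    SBP    DBP
        [1.00, -0.30,  0.30,  0.25,  0.25,  0.25],  # BMI
        [-0.30, 1.00, -0.45, -0.15, -0.10, -0.10],  # HDL
        [0.30, -0.45,  1.00,  0.20,  0.15,  0.15],  # TG
        [0.25, -0.15,  0.20,  1.00,  0.15,  0.10],  # GLU
        [0.25, -0.10,  0.15,  0.15,  1.00,  0.70],  # SBP
        [0.25, -0.10,  0.15,  0.10,  0.70,  1.00],  # DBP
    ])
    return pd.DataFrame(c, index=TRAITS, columns=TRAITS)


FAMILY_TYPES = ("trio", "nuclear-4", "three-generation-6")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Effect sizes (``effect_table`` betas) are in expression units (log2 for
    mRNA, Ct for miRNA before sign inversion) per trait standard deviation.
    """

    n_families: int = 100
    family_size_distribution: dict[str, float] = field(
        default_factory=lambda: {"trio": 0.4, "nuclear-4": 0.4,
                                 "three-generation-6": 0.2})
    n_mrna: int = 500
    n_mirna: int = 50
    trait_correlation: pd.DataFrame | None = None
    trait_heritability: float = 0.4
    heritability_expr: float = 0.3
    effect_table: list[tuple[str, str, float]] = field(default_factory=list)
    coexpression_table: list[tuple[str, str, float]] = field(default_factory=list)
    ct_detection_mean: float = 24.0
    ct_detection_sd: float = 2.0
    ct_threshold: float = 27.0
    batch_count: int = 4
    batch_sd: float = 0.3
    n_cell_types: int = 5
    cell_loading_genes: int = 30
    cell_noise_sd: float = 0.5
    expr_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_correlation is None:
            self.trait_correlation = default_trait_correlation()
        C = np.asarray(self.trait_correlation, dtype=float)
        if not np.allclose(C, C.T):
            raise ValueError("trait_correlation must be symmetric")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("trait_correlation must be positive definite")
        if not 0 <= self.heritability_expr < 1:
            raise ValueError("heritability_expr must lie in [0, 1)")
        if not 0 <= self.trait_heritability < 1:
            raise ValueError("trait_heritability must lie in [0, 1)")
        for t, tr, b in self.effect_table:
            if not np.isfinite(b):
                raise ValueError(f"non-finite beta for ({t}, {tr})")


@dataclass
class SyntheticTruth:
    """Ground truth planted into a cohort."""

    planted_effects: pd.DataFrame          # transcript_id, trait_id, beta, class
    pleiotropy_counts: pd.Series           # transcript_id -> n traits planted
    coexpression_pairs: pd.DataFrame       # mirna_id, mrna_id, slope

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.planted_effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        self.pleiotropy_counts.rename("n_traits").to_csv(
            outdir / "truth_pleiotropy.tsv", sep="\t")
        self.coexpression_pairs.to_csv(outdir / "truth_coexpression.tsv",
                                       sep="\t", index=False)


@dataclass
class SyntheticCohort:
    pedigree: Pedigree
    relationship: RelationshipMatrix
    phenotypes: pd.DataFrame               # samples x (traits + age/sex/batch + cells)
    mrna: pd.DataFrame                     # genes x samples, log2 scale
    ct: pd.DataFrame                       # miRNAs x samples, Ct scale, NaN = not detected
    latent_ct: pd.DataFrame                # pre-censoring Ct values
    truth: SyntheticTruth

    @property
    def samples(self) -> list[str]:
        return list(self.phenotypes.index)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write(outdir / "cohort.ped")
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t",
                               index_label="individual_id")
        self.mrna.to_csv(outdir / "mrna.tsv", sep="\t", index_label="transcript_id")
        self.ct.to_csv(outdir / "mirna_ct.tsv", sep="\t", index_label="mirna_id")
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _family_records(fam_id: str, ftype: str) -> list[PedigreeRecord]:
    f = fam_id
    if ftype == "trio":
        return [
            PedigreeRecord(f, f + "_pa", None, None, "male"),
            PedigreeRecord(f, f + "_ma", None, None, "female"),
            PedigreeRecord(f, f + "_c1", f + "_pa", f + "_ma", "female"),
        ]
    if ftype == "nuclear-4":
        return [
            PedigreeRecord(f, f + "_pa", None, None, "male"),
            PedigreeRecord(f, f + "_ma", None, None, "female"),
            PedigreeRecord(f, f + "_c1", f + "_pa", f + "_ma", "male"),
            PedigreeRecord(f, f + "_c2", f + "_pa", f + "_ma", "female"),
        ]
    if ftype == "three-generation-6":
        return [
            PedigreeRecord(f, f + "_gpa", None, None, "male"),
            PedigreeRecord(f, f + "_gma", None, None, "female"),
            PedigreeRecord(f, f + "_pa", f + "_gpa", f + "_gma", "male"),
            PedigreeRecord(f, f + "_ma", None, None, "female"),
            PedigreeRecord(f, f + "_c1", f + "_pa", f + "_ma", "male"),
            PedigreeRecord(f, f + "_c2", f + "_pa", f + "_ma", "female"),
        ]
    raise ValueError(f"unknown family type {ftype!r}")


def simulate_pedigree(n_families: int, family_size_distribution: dict[str, float],
                      rng: np.random.Generator) -> Pedigree:
    types = list(family_size_distribution)
    probs = np.array([family_size_distribution[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    records: list[PedigreeRecord] = []
    for k in range(n_families):
        ftype = types[rng.choice(len(types), p=probs)]
        records.extend(_family_records(f"F{k:04d}", ftype))
    return Pedigree(records)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _polygenic(L: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k independent draws from N(0, A), as an (n, k) matrix, via A = L L'."""
    return L @ rng.standard_normal((L.shape[1], k))


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-identical given the same config."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg.n_families, cfg.family_size_distribution, rng)
    A = additive_relationship(ped)
    n = ped.n
    samples = ped.individual_ids

    # Cholesky of A with a tiny jitter (A is PSD; duplicated founder blocks
    # can make it numerically semidefinite).
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))

    # --- traits: z = sqrt(h2) * g + sqrt(1-h2) * e, cross-trait correlation
    # applied identically to both components so the target correlation holds
    C = np.asarray(cfg.trait_correlation, dtype=float)
    Lc = np.linalg.cholesky(C)
    h2 = cfg.trait_heritability
    g = _polygenic(L, len(TRAITS), rng) @ Lc.T
    e = rng.standard_normal((n, len(TRAITS))) @ Lc.T
    z = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
    traits = pd.DataFrame(
        {t: TRAIT_MEANS[t] + TRAIT_SDS[t] * z[:, j] for j, t in enumerate(TRAITS)},
        index=samples)
    trait_z = pd.DataFrame(z, index=samples, columns=TRAITS)

    # --- covariates
    age = np.clip(rng.normal(49.0, 12.0, n), 20, 90)
    sex = np.array([1.0 if r.sex == "female" else 0.0 for r in ped.records])
    batch = rng.integers(0, cfg.batch_count, n)
    cells = rng.dirichlet(np.full(cfg.n_cell_types, 8.0), size=n)  # fractions
    cell_names = [f"cell{j}" for j in range(cfg.n_cell_types)]

    pheno = traits.copy()
    pheno["age"] = age
    pheno["sex"] = sex
    pheno["batch"] = batch.astype(float)
    for j, cn in enumerate(cell_names):
        pheno[cn] = cells[:, j]

    # --- mRNA matrix
    genes = [f"G{j:05d}" for j in range(cfg.n_mrna)]
    mrna_effects = {(t, tr): b for t, tr, b in cfg.effect_table if t.startswith("G")}
    base = rng.normal(8.0, 1.0, cfg.n_mrna)
    h2e = cfg.heritability_expr
    sig = cfg.expr_noise_sd
    G = _polygenic(L, cfg.n_mrna, rng)                    # N(0, A) per gene
    E = rng.standard_normal((n, cfg.n_mrna))
    expr = base[None, :] + sig * (np.sqrt(h2e) * G + np.sqrt(1 - h2e) * E)
    # batch shifts
    batch_eff = rng.normal(0.0, cfg.batch_sd, (cfg.batch_count, cfg.n_mrna))
    expr += batch_eff[batch]
    # age/sex nuisance on a random 20% of genes
    n_cov_genes = max(1, cfg.n_mrna // 5)
    cov_idx = rng.choice(cfg.n_mrna, n_cov_genes, replace=False)
    expr[:, cov_idx] += np.outer((age - 49.0) / 12.0,
                                 rng.normal(0.0, 0.15, n_cov_genes))
    expr[:, cov_idx] += np.outer(sex, rng.normal(0.0, 0.15, n_cov_genes))
    # cell-count loadings on the first cell_loading_genes genes: gives PLS
    # imputation real signal
    kload = min(cfg.cell_loading_genes, cfg.n_mrna)
    load = rng.normal(0.0, 4.0, (cfg.n_cell_types, kload))
    expr[:, :kload] += (cells - cells.mean(0)) @ load
    # planted trait effects
    gene_pos = {gname: j for j, gname in enumerate(genes)}
    for (t, tr), b in mrna_effects.items():
        expr[:, gene_pos[t]] += b * trait_z[tr].to_numpy()
    mrna = pd.DataFrame(expr.T, index=genes, columns=samples)

    # --- miRNA latent Ct
    mirs = [f"miR-{j:03d}" for j in range(cfg.n_mirna)]
    mir_effects = {(t, tr): b for t, tr, b in cfg.effect_table if t.startswith("miR")}
    mir_base = rng.normal(cfg.ct_detection_mean, cfg.ct_detection_sd, cfg.n_mirna)
    Gm = _polygenic(L, cfg.n_mirna, rng)
    Em = rng.standard_normal((n, cfg.n_mirna))
    ct_lat = mir_base[None, :] + sig * (np.sqrt(h2e) * Gm + np.sqrt(1 - h2e) * Em)
    mir_pos = {m: j for j, m in enumerate(mirs)}
    # sign inversion: a positive expression effect lowers Ct
    for (t, tr), b in mir_effects.items():
        ct_lat[:, mir_pos[t]] -= b * trait_z[tr].to_numpy()

    # --- planted miRNA -> mRNA coexpression (mRNA driven by latent Ct)
    coex_rows = []
    for mir, gname, slope in cfg.coexpression_table:
        zc = ct_lat[:, mir_pos[mir]]
        zc = (zc - zc.mean()) / zc.std()
        mrna.loc[gname] = mrna.loc[gname].to_numpy() + slope * zc
        coex_rows.append({"mirna_id": mir, "mrna_id": gname, "slope": slope})

    latent_ct = pd.DataFrame(ct_lat.T, index=mirs, columns=samples)
    ct, _ = censor_ct(latent_ct, cfg.ct_threshold)

    # --- truth tables
    eff = pd.DataFrame(
        [{"transcript_id": t, "trait_id": tr, "beta": b,
          "class": "mRNA" if t.startswith("G") else "miRNA"}
         for t, tr, b in cfg.effect_table])
    if eff.empty:
        eff = pd.DataFrame(columns=["transcript_id", "trait_id", "beta", "class"])
    pleio = (eff.groupby("transcript_id")["trait_id"].nunique()
             if not eff.empty else pd.Series(dtype=int))
    coex = pd.DataFrame(coex_rows, columns=["mirna_id", "mrna_id", "slope"])
    truth = SyntheticTruth(eff, pleio, coex)

    return SyntheticCohort(ped, A, pheno, mrna, ct, latent_ct, truth)


def confounded_expression_panel(
    n_samples: int = 200,
    n_mirna: int = 10,
    n_mrna: int = 40,
    confounder_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, RelationshipMatrix]:
    """Null miRNA/mRNA panel sharing one strong latent confounder.

    No miRNA truly regulates any mRNA: every apparent coexpression pair is
    induced by a sample-level latent factor (think processing batch or cell
    composition) loading on both matrices with sd ``confounder_sd``.  Used
    to demonstrate that surrogate-variable adjustment removes
    confounder-driven false pairs.  Kinship is identity (unrelated
    samples); all Ct values are detected.
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    factor = rng.standard_normal(n_samples)
    load_g = rng.normal(0.0, confounder_sd, n_mrna)
    load_m = rng.normal(0.0, confounder_sd, n_mirna)
    expr = pd.DataFrame(
        (8.0 + np.outer(factor, load_g) + rng.standard_normal((n_samples, n_mrna))).T,
        index=[f"G{j:03d}" for j in range(n_mrna)], columns=samples)
    ct = pd.DataFrame(
        (24.0 + np.outer(factor, load_m) + rng.standard_normal((n_samples, n_mirna))).T,
        index=[f"miR-{j:02d}" for j in range(n_mirna)], columns=samples)
    A = RelationshipMatrix(samples, np.eye(n_samples))
    return expr, ct, A


def censor_ct(latent_ct: pd.DataFrame, threshold: float
              ) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the detection limit: Ct >= threshold becomes missing.

    Returns the censored matrix and per-miRNA detection proportions.
    Observed (below-threshold) values are passed through unchanged.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    ct = latent_ct.where(latent_ct < threshold)
    detection = ct.notna().mean(axis=1)
    return ct, detection
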