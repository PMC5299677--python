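"""Simulation studies that characterize the pipeline's operating behaviour:
type-I error of the scan branches, power and sign accuracy on planted
effects, confounder removal by SV adjustment, and discovery/validation
replication.  These drivers are what the acceptance script and the
calibration tests run; every quantity is computed fresh from seeded
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association as assoc
from .association import EigenA, _design, _fit_rotated, attach_fdr
from .coexpression import pairwise_scan
from .covariates import assemble_covariates, estimate_svs, select_svs
from .pedigree import additive_relationship
from .simulate import (SimConfig, confounded_expression_panel, generate_cohort,
                       simulate_pedigree)

__all__ = [
    "linear_null_rejection",
    "combined_null_rejection",
    "planted_recovery",
    "pleiotropy_recovery",
    "coexpression_recovery",
    "confounder_reduction",
    "replication_rate",
]


def _nuclear_cohort_eig(n_families: int, seed: int):
    """Nuclear-family cohort scaffold: A, its eigendecomposition, a Cholesky
    factor for drawing family-correlated responses, and a fixed covariate."""
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(n_families, {"nuclear-4": 1.0}, rng)
    A = additive_relationship(ped)
    n = A.values.shape[0]
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
    eig = EigenA.from_matrix(A)
    trait = rng.standard_normal(n)
    return ped, A, eig, L, trait, rng


def linear_null_rejection(
    n_samples: int = 500,
    n_reps: int = 2000,
    alpha: float = 0.05,
    h2: float = 0.4,
    seed: int = 0,
) -> float:
    """Type-I error of the kinship-LMM Wald test under the null.

    Each replicate draws a family-correlated response (heritability ``h2``)
    independent of a fixed trait on a nuclear-family cohort and fits the
    LMM; returns the fraction of p-values below ``alpha``.  Responses are
    drawn directly in the eigenbasis (variance h2*d + (1-h2) per
    coordinate), which is exactly N(0, h2*A + (1-h2)*I) rotated.
    """
    ped, A, eig, L, trait, rng = _nuclear_cohort_eig(n_samples // 4, seed)
    n = eig.n
    d = eig.eigvals
    X = np.column_stack([np.ones(n), trait])
    Xt = eig.rotate(X)
    sd_rot = np.sqrt(h2 * d + (1.0 - h2))
    hits = 0
    for _ in range(n_reps):
        yt = sd_rot * rng.standard_normal(n)
        fit = _fit_rotated(d, yt, Xt)
        hits += fit.p < alpha
    return hits / n_reps


def combined_null_rejection(
    n_samples: int = 500,
    n_reps: int = 2000,
    detection: float = 0.5,
    alpha: float = 0.05,
    h2: float = 0.4,
    seed: int = 0,
) -> float:
    """Type-I error of the combined (2-df) two-part branch under the null.

    Latent Ct values are family-correlated and censored at their
    ``detection`` quantile, so each replicate has ~50% detection and the
    combined branch runs.  The two chi-square components share data and are
    not exactly independent, so modest calibration error is expected.
    """
    ped, A, eig, L, trait_arr, rng = _nuclear_cohort_eig(n_samples // 4, seed)
    n = len(ped.individual_ids)
    samples = ped.individual_ids
    trait = pd.Series(trait_arr, index=samples, name="T")
    hits = 0
    tested = 0
    for _ in range(n_reps):
        latent = 26.0 + np.sqrt(h2) * (L @ rng.standard_normal(n)) + \
            np.sqrt(1 - h2) * rng.standard_normal(n)
        thresh = np.quantile(latent, detection)
        ct = pd.Series(np.where(latent < thresh, latent, np.nan),
                       index=samples, name="m")
        r = assoc.two_part_test(ct, trait, None, A)
        if r.testable and r.p is not None:
            tested += 1
            hits += r.p < alpha
    return hits / max(tested, 1)


@dataclass
class RecoveryReport:
    power: float
    n_planted: int
    n_detected: int
    sign_errors: int
    fdr_threshold: float


def planted_recovery(
    n_families: int = 250,
    n_mrna: int = 200,
    n_planted: int = 20,
    beta: float = 0.3,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> RecoveryReport:
    """Power to recover planted transcript-trait effects at FDR control.

    ``n_planted`` transcripts carry an effect of ``beta`` expression-SD per
    trait-SD on BMI in a nuclear-family cohort (~4 x n_families samples);
    the rest are null.  Reports the fraction of planted transcripts at
    q < ``fdr_threshold`` and the number of detected effects whose
    estimated sign disagrees with the planted sign.
    """
    effects = [(f"G{i:05d}", "BMI", beta) for i in range(n_planted)]
    cfg = SimConfig(n_families=n_families,
                    family_size_distribution={"nuclear-4": 1.0},
                    n_mrna=n_mrna, n_mirna=2, effect_table=effects, seed=seed)
    cohort = generate_cohort(cfg)
    z = cohort.phenotypes["BMI"]
    z = (z - z.mean()) / z.std()
    res = assoc.scan_continuous(cohort.mrna, z,
                                cohort.phenotypes[["age", "sex"]],
                                cohort.relationship, trait_id="BMI")
    attach_fdr(res)
    planted = {e[0] for e in effects}
    detected = [r for r in res
                if r.transcript_id in planted and r.q is not None
                and r.q < fdr_threshold]
    sign_errors = sum(1 for r in detected if np.sign(r.beta) != np.sign(beta))
    return RecoveryReport(power=len(detected) / n_planted,
                          n_planted=n_planted, n_detected=len(detected),
                          sign_errors=sign_errors,
                          fdr_threshold=fdr_threshold)


def pleiotropy_recovery(
    n_families: int = 150,
    n_mrna: int = 100,
    beta: float = 0.6,
    q_threshold: float = 0.001,
    seed: int = 0,
) -> tuple[str, int]:
    """Plant one transcript on all six traits; return the top pleiotropy
    record (id, trait count) from the six-trait scan.

    Traits are simulated uncorrelated here: with correlated traits the six
    additive planted effects partially cancel in the marginal scans (the
    HDL slope becomes 0.6*(1 + sum of its negative correlations) ~ 0),
    which would test the trait model rather than the tallying logic.
    """
    from .pleiotropy import count_pleiotropy
    from .simulate import TRAITS
    effects = [("G00000", t, beta) for t in TRAITS]
    # a few partial-pleiotropy decoys
    effects += [("G00001", t, beta) for t in TRAITS[:3]]
    cfg = SimConfig(n_families=n_families,
                    family_size_distribution={"nuclear-4": 1.0},
                    n_mrna=n_mrna, n_mirna=2, effect_table=effects,
                    trait_correlation=pd.DataFrame(np.eye(6), index=TRAITS,
                                                   columns=TRAITS),
                    seed=seed)
    cohort = generate_cohort(cfg)
    eig = EigenA.from_matrix(cohort.relationship)
    results = []
    for t in TRAITS:
        z = cohort.phenotypes[t]
        z = (z - z.mean()) / z.std()
        results.extend(assoc.scan_continuous(
            cohort.mrna, z, cohort.phenotypes[["age", "sex"]], eig,
            trait_id=t))
    attach_fdr(results)
    records = count_pleiotropy(results, q_threshold)
    top = records[0]
    return top.transcript_id, top.count


def coexpression_recovery(
    n_families: int = 250,
    n_mrna: int = 60,
    n_mirna: int = 10,
    slope: float = 0.5,
    seed: int = 0,
) -> tuple[float, bool]:
    """Recover a planted miRNA-mRNA pair: returns (its q, recovered flag)."""
    cfg = SimConfig(n_families=n_families,
                    family_size_distribution={"nuclear-4": 1.0},
                    n_mrna=n_mrna, n_mirna=n_mirna,
                    coexpression_table=[("miR-000", "G00010", slope)],
                    ct_detection_mean=23.0, seed=seed)
    cohort = generate_cohort(cfg)
    n = len(cohort.samples)
    pairs = pairwise_scan(cohort.mrna, cohort.ct,
                          cohort.phenotypes[["age", "sex"]],
                          cohort.relationship, min_samples=n // 2)
    hit = next(p for p in pairs
               if p.mirna_id == "miR-000" and p.mrna_id == "G00010")
    return float(hit.q), bool(hit.significant)


def confounder_reduction(
    n_seeds: int = 50,
    n_samples: int = 200,
    n_mirna: int = 10,
    n_mrna: int = 40,
    seed: int = 0,
) -> tuple[int, float, float]:
    """SV adjustment vs confounded null panels over ``n_seeds`` seeds.

    Returns (#seeds where SV adjustment strictly reduced false pairs,
    mean false pairs without SVs, mean with SVs).  Every significant pair
    on these panels is false by construction.
    """
    strict = 0
    tot_without = 0
    tot_with = 0
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31 - 1)
    for s in range(n_seeds):
        expr, ct, A = confounded_expression_panel(
            n_samples=n_samples, n_mirna=n_mirna, n_mrna=n_mrna,
            seed=int(base + s))
        min_samples = n_samples // 2
        no_sv = pairwise_scan(expr, ct, None, A, min_samples=min_samples)
        n_without = sum(p.significant for p in no_sv)
        svs = estimate_svs(expr, np.ones((n_samples, 1)), k=3, seed=s)
        svs = select_svs(svs, ct, A, alpha_family=0.05)
        if svs.selected().shape[1]:
            cov = assemble_covariates(pd.DataFrame(index=expr.columns), [],
                                      svs=svs)
        else:
            cov = None
        with_sv = pairwise_scan(expr, ct, cov, A, min_samples=min_samples)
        n_with = sum(p.significant for p in with_sv)
        strict += n_with < n_without
        tot_without += n_without
        tot_with += n_with
    return strict, tot_without / n_seeds, tot_with / n_seeds


def replication_rate(
    n_families: int = 250,
    n_mrna: int = 150,
    n_planted: int = 20,
    beta: float = 0.4,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Discovery -> validation replication of planted effects.

    The cohort is split family-wise; planted transcripts significant in the
    discovery scan (q < threshold) are re-tested in the validation set with
    its own FDR.  Returns (fraction revalidated, #discovered planted)."""
    effects = [(f"G{i:05d}", "BMI", beta) for i in range(n_planted)]
    cfg = SimConfig(n_families=n_families,
                    family_size_distribution={"nuclear-4": 1.0},
                    n_mrna=n_mrna, n_mirna=2, effect_table=effects, seed=seed)
    cohort = generate_cohort(cfg)
    split = assoc.split_discovery_validation(cohort.pedigree, seed)
    planted = {e[0] for e in effects}

    def scan_subset(label):
        sub = [s for s in cohort.samples if split.sample_sets[s] == label]
        z = cohort.phenotypes.loc[sub, "BMI"]
        z = (z - z.mean()) / z.std()
        res = assoc.scan_continuous(cohort.mrna[sub], z,
                                    cohort.phenotypes.loc[sub, ["age", "sex"]],
                                    cohort.relationship.subset(sub),
                                    trait_id="BMI")
        attach_fdr(res)
        return {r.transcript_id: r for r in res}

    disc = scan_subset("discovery")
    valid = scan_subset("validation")
    discovered = [t for t in planted
                  if disc[t].q is not None and disc[t].q < fdr_threshold]
    if not discovered:
        return 0.0, 0
    revalidated = [t for t in discovered
                   if valid[t].q is not None and valid[t].q < fdr_threshold
                   and np.sign(valid[t].beta) == np.sign(disc[t].beta)]
    return len(revalidated) / len(discovered), len(discovered)
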