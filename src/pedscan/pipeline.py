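"""Config-driven end-to-end pipeline with a reproducibility manifest.

Stage order: simulate (or load) -> covariates -> trait scans (full cohort
and, optionally, a pedigree-preserving discovery/validation split) ->
coexpression -> pleiotropy/network -> enrichment.  Every threshold the
analysis uses (Ct detection limit 27, the 90%/10% branch rule, per-class
pleiotropy FDR cutoffs 0.001/0.05, coexpression FDR 0.05, SV-selection
alpha 0.05 over the miRNA panel, gene-set alpha 0.05 over the collection,
panel filters 100/200) lives in the config with those defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import covariates as cov
from .coexpression import pairs_frame, pairwise_scan, per_mirna_counts
from .enrichment import enrichment_frame, fisher_enrichment, read_gmt
from .pedigree import RelationshipMatrix, additive_relationship, read_pedigree
from .pleiotropy import (annotate_targets, count_pleiotropy, edges_frame,
                         pleiotropy_frame, read_target_table, trait_similarity)
from .simulate import TRAITS, SimConfig, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "default_config"]

logger = logging.getLogger(__name__)


DEFAULT_THRESHOLDS = {
    "ct_threshold": 27.0,
    "branch_high": 0.90,
    "branch_low": 0.10,
    "fdr_mrna_pleiotropy": 0.001,
    "fdr_mirna_pleiotropy": 0.05,
    "fdr_coexpression": 0.05,
    "sv_alpha_family": 0.05,
    "go_alpha_family": 0.05,
    "min_detection_panel": 100,
    "min_detection_coexpression": 200,
}


@dataclass
class PipelineConfig:
    out_dir: str = "pedscan_run"
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    covariate_columns: list[str] = field(default_factory=lambda: ["age", "sex", "batch"])
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    simulate: dict | None = None          # SimConfig fields, or None to load inputs
    inputs: dict | None = None            # paths: ped, pheno, mrna, ct, gmt, targets
    split: bool = False
    n_svs: int | str = 0                  # 0 = skip SVA; "auto" = parallel analysis
    stages: list[str] = field(default_factory=lambda: [
        "cohort", "covariates", "scan", "coexpress", "pleiotropy", "enrich"])

    def __post_init__(self) -> None:
        bad_thr = set(self.thresholds or {}) - set(DEFAULT_THRESHOLDS)
        if bad_thr:
            raise ValueError(f"unknown threshold keys: {sorted(bad_thr)}")
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds or {})
        self.thresholds = thr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bad = set(raw) - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def default_config() -> PipelineConfig:
    return PipelineConfig(simulate={"n_families": 60, "n_mrna": 300, "n_mirna": 30})


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_hashes: dict
    outputs: list[str]
    stage_rows: dict
    stage_seconds: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        # timings stay out of the file so identical runs give identical manifests
        payload = asdict(self)
        payload.pop("stage_seconds", None)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | str | Path) -> RunManifest:
    """Execute the configured stages in dependency order.

    Deterministic given the config (all randomness flows from its seed);
    re-running the same config reproduces identical outputs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cfgd = config
    out = Path(cfgd.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfgd.thresholds
    timings: dict[str, float] = {}
    rows: dict[str, int] = {}
    outputs: list[str] = []
    input_hashes: dict[str, str] = {}

    def _emit(df: pd.DataFrame, name: str, **to_csv_kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=to_csv_kw.pop("index", False), **to_csv_kw)
        outputs.append(str(path))

    # ---- stage: cohort -----------------------------------------------------
    t0 = time.perf_counter()
    if cfgd.simulate is not None:
        sim_kwargs = dict(cfgd.simulate)
        sim_kwargs.setdefault("seed", cfgd.seed)
        sim_kwargs.setdefault("ct_threshold", thr["ct_threshold"])
        sim = SimConfig(**sim_kwargs)
        cohort = generate_cohort(sim)
        ped, A = cohort.pedigree, cohort.relationship
        pheno, mrna, ct = cohort.phenotypes, cohort.mrna, cohort.ct
        if "cohort" in cfgd.stages:
            cohort.write(out / "cohort")
            outputs.append(str(out / "cohort"))
    else:
        if not cfgd.inputs:
            raise ValueError("config needs either 'simulate' or 'inputs'")
        paths = {k: Path(v) for k, v in cfgd.inputs.items()}
        for k, p in paths.items():
            if k in ("ped", "pheno", "mrna", "ct") and not p.exists():
                raise FileNotFoundError(f"input {k!r} missing: {p}")
            if p.exists():
                input_hashes[k] = _hash_file(p)
        ped = read_pedigree(paths["ped"])
        A = additive_relationship(ped)
        pheno = pd.read_csv(paths["pheno"], sep="\t", index_col=0)
        pheno.index = pheno.index.astype(str)
        mrna = pd.read_csv(paths["mrna"], sep="\t", index_col=0)
        ct = pd.read_csv(paths["ct"], sep="\t", index_col=0)
    samples = [s for s in ped.individual_ids if s in pheno.index]
    pheno = pheno.loc[samples]
    mrna = mrna[samples]
    ct = ct[samples]
    A = A.subset(samples)
    timings["cohort"] = time.perf_counter() - t0
    rows["cohort"] = len(samples)

    # panel filter: miRNAs detected in at least min_detection_panel samples
    panel_min = int(thr["min_detection_panel"])
    detected = ct.notna().sum(axis=1)
    ct_panel = ct.loc[detected >= panel_min]
    rows["mirna_panel"] = ct_panel.shape[0]

    # ---- stage: covariates -------------------------------------------------
    t0 = time.perf_counter()
    covariates = pheno[cfgd.covariate_columns].copy()
    svset = None
    if cfgd.n_svs and "covariates" in cfgd.stages:
        M = np.column_stack([np.ones(len(samples)),
                             covariates.to_numpy(dtype=float)])
        svset = cov.estimate_svs(mrna, M, k=cfgd.n_svs, seed=cfgd.seed)
        if svset.k and ct_panel.shape[0]:
            svset = cov.select_svs(svset, ct_panel, A,
                                   alpha_family=thr["sv_alpha_family"])
            svset.write_tsv(out / "surrogate_variables.tsv")
            outputs.append(str(out / "surrogate_variables.tsv"))
    coex_covariates = cov.assemble_covariates(pheno, cfgd.covariate_columns,
                                              svs=svset)
    timings["covariates"] = time.perf_counter() - t0

    # ---- stage: scan -------------------------------------------------------
    scan_results_mrna: list[assoc.AssociationResult] = []
    scan_results_mirna: list[assoc.AssociationResult] = []
    if "scan" in cfgd.stages:
        t0 = time.perf_counter()
        eig = assoc.EigenA.from_matrix(A)
        subsets = {"full": samples}
        if cfgd.split:
            split = assoc.split_discovery_validation(ped, cfgd.seed)
            subsets["discovery"] = [s for s in samples
                                    if split.sample_sets[s] == "discovery"]
            subsets["validation"] = [s for s in samples
                                     if split.sample_sets[s] == "validation"]
            pd.Series(split.sample_sets, name="set").loc[samples].to_csv(
                out / "split.tsv", sep="\t", index_label="individual_id")
            outputs.append(str(out / "split.tsv"))
        for label, subset in subsets.items():
            sub_eig = eig if label == "full" else assoc.EigenA.from_matrix(
                A.subset(subset))
            m_res: list[assoc.AssociationResult] = []
            mi_res: list[assoc.AssociationResult] = []
            for trait in cfgd.traits:
                tvec = pheno.loc[subset, trait]
                cvs = covariates.loc[subset]
                m_res.extend(assoc.scan_continuous(mrna[subset], tvec, cvs,
                                                   sub_eig, trait_id=trait))
                mi_res.extend(assoc.scan_two_part(
                    ct_panel[subset], tvec, cvs, A.subset(subset),
                    threshold_high=thr["branch_high"],
                    threshold_low=thr["branch_low"], trait_id=trait))
            assoc.attach_fdr(m_res)
            assoc.attach_fdr(mi_res)
            _emit(assoc.results_frame(m_res), f"scan_mrna_{label}.tsv")
            _emit(assoc.results_frame(mi_res), f"scan_mirna_{label}.tsv")
            if label == "full":
                scan_results_mrna, scan_results_mirna = m_res, mi_res
        timings["scan"] = time.perf_counter() - t0
        rows["scan_mrna"] = len(scan_results_mrna)
        rows["scan_mirna"] = len(scan_results_mirna)

    # ---- stage: coexpress --------------------------------------------------
    coex_pairs = []
    if "coexpress" in cfgd.stages:
        t0 = time.perf_counter()
        coex_min = int(thr["min_detection_coexpression"])
        eligible = ct.loc[ct.notna().sum(axis=1) > coex_min]
        if eligible.shape[0]:
            coex_pairs = pairwise_scan(
                mrna, eligible, coex_covariates, A,
                min_samples=coex_min, fdr_threshold=thr["fdr_coexpression"])
            _emit(pairs_frame(coex_pairs), "coexpression_pairs.tsv")
            with open(out / "coexpression_summary.json", "w") as fh:
                json.dump(per_mirna_counts(coex_pairs), fh, indent=2)
            outputs.append(str(out / "coexpression_summary.json"))
        timings["coexpress"] = time.perf_counter() - t0
        rows["coexpression_pairs"] = len(coex_pairs)

    # ---- stage: pleiotropy -------------------------------------------------
    if "pleiotropy" in cfgd.stages and scan_results_mrna:
        t0 = time.perf_counter()
        pleio_m = count_pleiotropy(scan_results_mrna, thr["fdr_mrna_pleiotropy"])
        _emit(pleiotropy_frame(pleio_m), "pleiotropy_mrna.tsv")
        if scan_results_mirna:
            pleio_mi = count_pleiotropy(scan_results_mirna,
                                        thr["fdr_mirna_pleiotropy"])
            _emit(pleiotropy_frame(pleio_mi), "pleiotropy_mirna.tsv")
        if len(cfgd.traits) >= 2:
            edges = trait_similarity(scan_results_mrna,
                                     thr["fdr_mrna_pleiotropy"])
            _emit(edges_frame(edges), "trait_network_mrna.tsv")
        if cfgd.inputs and "targets" in cfgd.inputs and coex_pairs:
            targets = read_target_table(cfgd.inputs["targets"])
            annotated, n_overlap = annotate_targets(coex_pairs, targets)
            _emit(annotated, "coexpression_targets.tsv")
        timings["pleiotropy"] = time.perf_counter() - t0

    # ---- stage: enrich -----------------------------------------------------
    if ("enrich" in cfgd.stages and cfgd.inputs and "gmt" in cfgd.inputs
            and coex_pairs):
        t0 = time.perf_counter()
        collection = read_gmt(cfgd.inputs["gmt"]).restrict(mrna.index)
        sig_genes = {p.mrna_id for p in coex_pairs if p.significant}
        if collection.n_terms and sig_genes:
            res = fisher_enrichment(sig_genes, collection,
                                    alpha=thr["go_alpha_family"])
            _emit(enrichment_frame(res), "enrichment.tsv")
        timings["enrich"] = time.perf_counter() - t0

    manifest = RunManifest(
        config={**{k: v for k, v in asdict(cfgd).items()}},
        seed=cfgd.seed, input_hashes=input_hashes, outputs=sorted(outputs),
        stage_rows=rows,
        stage_seconds={k: round(v, 3) for k, v in timings.items()})
    manifest.write(out / "manifest.json")
    for stage, sec in timings.items():
        logger.info("stage %-12s %.2fs", stage, sec)
    return manifest
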