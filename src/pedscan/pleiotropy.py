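"""Pleiotropy tallies, trait-similarity networks, and target annotation.

A transcript's pleiotropy is the number of traits with which it associates
below an FDR threshold (0.001 for mRNA scans, 0.05 for miRNA scans by
default).  Trait similarity is the overlap of significant transcript sets
between trait pairs; sign concordance is the fraction of shared
transcripts whose effect directions agree, on the expression scale (Ct
effects are negated so "positive" always means co-increase in expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationResult
from .coexpression import CoexpressionPair

__all__ = [
    "PleiotropyRecord",
    "TraitEdge",
    "count_pleiotropy",
    "trait_similarity",
    "trait_network",
    "annotate_targets",
    "normalize_mirna_id",
]


@dataclass
class PleiotropyRecord:
    transcript_id: str
    transcript_class: str                  # mRNA | miRNA
    traits_significant: set[str]
    count: int
    direction: dict[str, int]              # trait -> sign on the expression scale
    min_q: float


@dataclass
class TraitEdge:
    trait_a: str
    trait_b: str
    shared_count: int
    sign_concordance: float | None         # None when no transcript is shared


def _expression_sign(r: AssociationResult, transcript_class: str) -> int:
    """Effect sign on the expression scale; Ct-branch betas are negated."""
    beta = r.beta
    if beta is None or (isinstance(beta, float) and np.isnan(beta)):
        beta = r.beta_logistic if r.beta_logistic is not None else 0.0
    s = int(np.sign(beta))
    if transcript_class == "miRNA" and r.branch != "logistic":
        s = -s  # higher Ct = lower expression
    return s


def _infer_class(results: Sequence[AssociationResult]) -> str:
    branches = {r.branch for r in results}
    if branches <= {"lmm"}:
        return "mRNA"
    if branches <= {"linear", "logistic", "combined"}:
        return "miRNA"
    raise ValueError(f"mixed transcript classes in results: branches {branches}")


def count_pleiotropy(
    results: Sequence[AssociationResult],
    q_threshold: float,
) -> list[PleiotropyRecord]:
    """Per-transcript count of traits significant at q < q_threshold.

    Results must come from a single transcript class (one scan family);
    mixing mRNA and miRNA scans raises.  Output is sorted by count
    descending, ties broken by the smallest q.
    """
    if not results:
        return []
    tclass = _infer_class(results)
    by_transcript: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_transcript.setdefault(r.transcript_id, []).append(r)
    records = []
    for tid, rs in by_transcript.items():
        sig = [r for r in rs
               if r.testable and r.q is not None and r.q < q_threshold]
        traits = {r.trait_id for r in sig}
        direction = {r.trait_id: _expression_sign(r, tclass) for r in sig}
        qs = [r.q for r in rs if r.q is not None]
        records.append(PleiotropyRecord(
            transcript_id=tid, transcript_class=tclass,
            traits_significant=traits, count=len(traits),
            direction=direction, min_q=min(qs) if qs else np.nan))
    records.sort(key=lambda rec: (-rec.count, rec.min_q))
    return records


def trait_similarity(
    results: Sequence[AssociationResult],
    q_threshold: float,
) -> list[TraitEdge]:
    """Shared-transcript counts and sign concordance for every trait pair."""
    if not results:
        return []
    tclass = _infer_class(results)
    traits = sorted({r.trait_id for r in results})
    if len(traits) < 2:
        raise ValueError("need results for at least two traits")
    sig: dict[str, dict[str, int]] = {t: {} for t in traits}
    for r in results:
        if r.testable and r.q is not None and r.q < q_threshold:
            sig[r.trait_id][r.transcript_id] = _expression_sign(r, tclass)
    edges = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            shared = set(sig[a]) & set(sig[b])
            if shared:
                agree = sum(1 for t in shared if sig[a][t] * sig[b][t] > 0)
                conc = agree / len(shared)
            else:
                conc = None
            edges.append(TraitEdge(a, b, len(shared), conc))
    return edges


def trait_network(edges: Sequence[TraitEdge]) -> nx.Graph:
    """Similarity graph: nodes = traits, edge weight = shared transcript count."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.trait_a)
        g.add_node(e.trait_b)
        if e.shared_count > 0:
            g.add_edge(e.trait_a, e.trait_b, weight=e.shared_count,
                       sign_concordance=e.sign_concordance)
    return g


def edges_frame(edges: Sequence[TraitEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait_a": [e.trait_a for e in edges],
            "trait_b": [e.trait_b for e in edges],
            "shared_count": [e.shared_count for e in edges],
            "sign_concordance": [e.sign_concordance for e in edges],
        }
    )


def pleiotropy_frame(records: Sequence[PleiotropyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "class": [r.transcript_class for r in records],
            "count": [r.count for r in records],
            "traits": [",".join(sorted(r.traits_significant)) for r in records],
            "directions": [",".join(f"{t}:{s:+d}" for t, s in sorted(r.direction.items()))
                           for r in records],
            "min_q": [r.min_q for r in records],
        }
    )


# ---------------------------------------------------------------------------
# target annotation
# ---------------------------------------------------------------------------

def normalize_mirna_id(mid: str) -> str:
    """Case-fold and strip the species prefix; arm suffixes are preserved.

    "hsa-miR-505-5p" and "MIR-505-5P" both normalize to "mir-505-5p".
    """
    m = mid.strip().lower()
    if m.startswith("hsa-"):
        m = m[4:]
    return m


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Flat miRNA->gene target-pair table: mirna_id, gene_symbol, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_symbol", "source"}
    if not required <= set(df.columns):
        raise ValueError(f"target table needs columns {sorted(required)}")
    return df


def annotate_targets(
    pairs: Sequence[CoexpressionPair],
    targets: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Flag coexpression pairs that are also predicted target pairs.

    Matching is case-insensitive on both ids, species prefix stripped from
    the miRNA; gene symbols are upper-cased.  Returns the annotated pair
    table and the count of significant pairs supported by at least one
    target source.
    """
    lut: dict[tuple[str, str], list[str]] = {}
    for _, row in targets.iterrows():
        key = (normalize_mirna_id(str(row["mirna_id"])),
               str(row["gene_symbol"]).strip().upper())
        lut.setdefault(key, []).append(str(row["source"]))
    rows = []
    n_overlap = 0
    for p in pairs:
        key = (normalize_mirna_id(p.mirna_id), p.mrna_id.strip().upper())
        sources = sorted(set(lut.get(key, [])))
        is_target = bool(sources)
        if is_target and p.significant:
            n_overlap += 1
        rows.append({
            "mirna_id": p.mirna_id, "mrna_id": p.mrna_id, "q": p.q,
            "significant": p.significant, "is_target": is_target,
            "sources": ";".join(sources),
        })
    return pd.DataFrame(rows), n_overlap
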