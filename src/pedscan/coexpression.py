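"""Pairwise miRNA-mRNA coexpression with SV adjustment.

Each pair is a kinship LMM with the mRNA (log2 intensity) as response and
the miRNA Ct value as predictor, adjusted for the assembled covariates
(age, sex, technical covariates, cell counts, selected SVs), fitted on the
samples where the miRNA is detected.  BH FDR is computed over the full
pair list jointly; pairs pass at q < 0.05.

Effect signs: beta is on the Ct scale (log2 units per Ct); because higher
Ct means lower miRNA expression, the expression-direction effect is -beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import EigenA, _design, _fit_rotated, bh_fdr
from .pedigree import RelationshipMatrix

__all__ = ["CoexpressionPair", "pairwise_scan", "pairs_frame", "per_mirna_counts"]


@dataclass
class CoexpressionPair:
    mirna_id: str
    mrna_id: str
    n_used: int
    beta: float                # log2 expression units per Ct unit
    se: float
    p: float
    q: float | None = None
    significant: bool = False


def _scan_one_mirna(expr: pd.DataFrame, row: pd.Series,
                    covariates: pd.DataFrame | None,
                    A: RelationshipMatrix) -> list[CoexpressionPair]:
    det = row.notna()
    sub = list(row.index[det])
    eig = EigenA.from_matrix(A.subset(sub))
    ct_vec = row[det].to_numpy(dtype=float)
    cov_sub = covariates.loc[sub] if covariates is not None else None
    X = _design(ct_vec, cov_sub)
    Xt = eig.rotate(X)
    Yt = eig.rotate(expr[sub].to_numpy(dtype=float).T)
    d = eig.eigvals
    out = []
    for gi, gene in enumerate(expr.index):
        fit = _fit_rotated(d, Yt[:, gi], Xt)
        out.append(CoexpressionPair(
            mirna_id=str(row.name), mrna_id=str(gene), n_used=len(sub),
            beta=fit.beta, se=fit.se, p=fit.p))
    return out


def pairwise_scan(
    expr: pd.DataFrame,
    ct: pd.DataFrame,
    covariates: pd.DataFrame | None,
    A: RelationshipMatrix,
    min_samples: int = 200,
    fdr_threshold: float = 0.05,
    mirna_ids: Sequence[str] | None = None,
    n_jobs: int = 1,
) -> list[CoexpressionPair]:
    """All miRNA x mRNA pair fits, BH-corrected jointly.

    miRNAs detected in at most ``min_samples`` samples are excluded (the
    coexpression expression filter).  For each retained miRNA the kinship
    matrix is restricted to its detected samples and eigendecomposed once;
    every mRNA is then fitted in the rotated basis, so the per-pair cost is
    a 1-D REML optimization.  The scan partitions over miRNAs
    (``n_jobs`` workers); results are independent of the partitioning
    because FDR is applied once over the merged pair list.
    """
    mirnas = list(mirna_ids) if mirna_ids is not None else list(ct.index)
    detected_counts = ct.loc[mirnas].notna().sum(axis=1)
    keep = [m for m in mirnas if detected_counts[m] > min_samples]
    if not keep:
        raise ValueError(
            f"no miRNA detected in more than {min_samples} samples")

    if n_jobs == 1:
        chunks = [_scan_one_mirna(expr, ct.loc[mir], covariates, A)
                  for mir in keep]
    else:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_scan_one_mirna)(expr, ct.loc[mir], covariates, A)
            for mir in keep)
    pairs: list[CoexpressionPair] = [p for chunk in chunks for p in chunk]

    q = bh_fdr([p.p for p in pairs])
    for pair, qi in zip(pairs, q):
        pair.q = float(qi)
        pair.significant = bool(qi < fdr_threshold)
    return pairs


def pairs_frame(pairs: Sequence[CoexpressionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [p.mirna_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "n_used": [p.n_used for p in pairs],
            "beta": [p.beta for p in pairs],
            "se": [p.se for p in pairs],
            "p": [p.p for p in pairs],
            "q": [p.q for p in pairs],
            "significant": [p.significant for p in pairs],
        }
    )


def per_mirna_counts(pairs: Sequence[CoexpressionPair]) -> dict[str, int]:
    """Significant coexpressed-mRNA count per miRNA (summary JSON payload)."""
    out: dict[str, int] = {}
    for p in pairs:
        if p.significant:
            out[p.mirna_id] = out.get(p.mirna_id, 0) + 1
    return out
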