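"""Shared helper: false-pair counts on a confounded null panel, with and
without surrogate-variable adjustment."""

import numpy as np
import pandas as pd

from pedscan.coexpression import pairwise_scan
from pedscan.covariates import estimate_svs, select_svs, assemble_covariates
from pedscan.simulate import confounded_expression_panel


def false_pair_counts(seed: int, n_samples: int = 200, n_mirna: int = 10,
                      n_mrna: int = 40) -> tuple[int, int]:
    """(# significant pairs without SVs, # with selected SVs); all pairs on
    this panel are false by construction."""
    expr, ct, A = confounded_expression_panel(
        n_samples=n_samples, n_mirna=n_mirna, n_mrna=n_mrna, seed=seed)
    min_samples = n_samples // 2

    no_sv = pairwise_scan(expr, ct, None, A, min_samples=min_samples)
    n_without = sum(p.significant for p in no_sv)

    M = np.ones((n_samples, 1))
    svs = estimate_svs(expr, M, k=3, seed=seed)
    svs = select_svs(svs, ct, A, alpha_family=0.05)
    pheno = pd.DataFrame(index=expr.columns)
    cov = assemble_covariates(pheno, [], svs=svs) if svs.selected().shape[1] else None
    with_sv = pairwise_scan(expr, ct, cov, A, min_samples=min_samples)
    n_with = sum(p.significant for p in with_sv)
    return n_without, n_with
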