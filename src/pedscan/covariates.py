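"""Covariate assembly: PLS-imputed differential cell counts and surrogate
variables with Bonferroni miRNA-association selection.

Surrogate variables (SVs) capture hidden structure (batch, cell
composition, processing effects) left in the mRNA matrix after removing
known covariates.  We use the two-step residual-SVD construction:
residualize expression on the known model matrix, take the top right
singular vectors of the residual matrix (unit-norm, mutually orthogonal
sample-space components), and choose the dimension by permutation parallel
analysis when not fixed.  An SV is *selected* for the coexpression model
when it associates with at least one miRNA below alpha_family / n_miRNA —
with the defaults alpha 0.05 over 280 miRNAs this realizes the
1.79e-4 Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .association import scan_two_part
from .pedigree import RelationshipMatrix

__all__ = [
    "SurrogateVariableSet",
    "impute_cell_counts",
    "estimate_svs",
    "select_svs",
    "sv_bonferroni_threshold",
    "assemble_covariates",
]


# ---------------------------------------------------------------------------
# PLS cell-count imputation
# ---------------------------------------------------------------------------

def impute_cell_counts(
    expr: pd.DataFrame,
    training: pd.DataFrame,
    n_components: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Impute differential cell counts from mRNA expression by PLS.

    One PLS regression per cell type, trained on the samples present in
    ``training`` (samples x cell types) and predicted for every column of
    ``expr`` (genes x samples).  Accuracy is the cross-validated Pearson
    correlation between measured and predicted counts on the training set.

    Returns (imputed counts for all samples, cv_accuracy per cell type).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    train_samples = [s for s in training.index if s in expr.columns]
    if len(train_samples) < 10 * n_components:
        raise ValueError(
            f"training set ({len(train_samples)}) smaller than 10 x n_components")
    if n_components >= len(train_samples):
        raise ValueError("n_components must be below the training sample count")

    X_all = expr.to_numpy(dtype=float).T               # samples x genes
    sample_pos = {s: i for i, s in enumerate(expr.columns)}
    tr_idx = np.array([sample_pos[s] for s in train_samples])
    X_tr = X_all[tr_idx]

    imputed = {}
    acc = {}
    for cell in training.columns:
        y = training.loc[train_samples, cell].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"cell type {cell!r} has zero variance in training data")
        # cross-validated accuracy
        preds = np.empty_like(y)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in kf.split(X_tr):
            m = PLSRegression(n_components=n_components).fit(X_tr[tr], y[tr])
            preds[te] = m.predict(X_tr[te]).ravel()
        acc[cell] = float(stats.pearsonr(y, preds)[0])
        # final model on the full training set, predictions everywhere
        m = PLSRegression(n_components=n_components).fit(X_tr, y)
        imputed[cell] = m.predict(X_all).ravel()

    imputed_df = pd.DataFrame(imputed, index=list(expr.columns))
    return imputed_df, pd.Series(acc, name="cv_accuracy")


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

@dataclass
class SurrogateVariableSet:
    """Orthonormal sample-space surrogate variables with selection state."""

    sv_matrix: pd.DataFrame                # samples x k, unit-norm columns
    selected_flags: pd.Series | None = None
    min_p: pd.Series | None = None         # per-SV minimum p against miRNAs
    selection_alpha: float | None = None

    @property
    def k(self) -> int:
        return self.sv_matrix.shape[1]

    def selected(self) -> pd.DataFrame:
        if self.selected_flags is None:
            return self.sv_matrix
        return self.sv_matrix.loc[:, self.selected_flags[self.selected_flags].index]

    def write_tsv(self, path) -> None:
        df = self.sv_matrix.copy()
        out = df.T
        out.insert(0, "selected",
                   self.selected_flags.reindex(df.columns).fillna(False).to_numpy()
                   if self.selected_flags is not None else True)
        out.insert(1, "min_p",
                   self.min_p.reindex(df.columns).to_numpy()
                   if self.min_p is not None else np.nan)
        out.to_csv(path, sep="\t", index_label="sv")


def _residualize(expr: pd.DataFrame, model_matrix: np.ndarray) -> np.ndarray:
    """Residual of the samples x genes matrix on the known covariates."""
    Y = expr.to_numpy(dtype=float).T                   # samples x genes
    M = np.asarray(model_matrix, dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("model matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    return Y - M @ beta


def estimate_svs(
    expr: pd.DataFrame,
    model_matrix: np.ndarray | pd.DataFrame,
    k: int | str = "auto",
    n_permutations: int = 50,
    quantile: float = 0.95,
    seed: int = 0,
) -> SurrogateVariableSet:
    """Residual-SVD surrogate variables from the mRNA matrix.

    With ``k="auto"`` the dimension is chosen by permutation parallel
    analysis: each gene's residual vector is independently permuted across
    samples ``n_permutations`` times, and a component is kept while its
    singular value exceeds the permutation ``quantile`` of the matching
    order statistic.
    """
    if isinstance(model_matrix, pd.DataFrame):
        model_matrix = model_matrix.to_numpy(dtype=float)
    R = _residualize(expr, model_matrix)               # samples x genes
    n = R.shape[0]
    max_k = min(R.shape) - 1
    if isinstance(k, int) and k > max_k:
        raise ValueError(f"k={k} exceeds min(samples, transcripts)-1={max_k}")

    U, s, _ = np.linalg.svd(R, full_matrices=False)
    if k == "auto":
        rng = np.random.default_rng(seed)
        perm_s = np.empty((n_permutations, s.shape[0]))
        Rp = R.copy()
        for b in range(n_permutations):
            for j in range(Rp.shape[1]):
                rng.shuffle(Rp[:, j])
            perm_s[b] = np.linalg.svd(Rp, compute_uv=False)
        thresh = np.quantile(perm_s, quantile, axis=0)
        keep = 0
        while keep < s.shape[0] and s[keep] > thresh[keep]:
            keep += 1
        k = keep
    sv = U[:, :k]                                       # orthonormal columns
    cols = [f"SV{j + 1}" for j in range(k)]
    return SurrogateVariableSet(
        pd.DataFrame(sv, index=list(expr.columns), columns=cols))


def sv_bonferroni_threshold(alpha_family: float, n_mirna: int) -> float:
    """Per-test threshold for SV selection: alpha_family / n_miRNA."""
    if n_mirna <= 0:
        raise ValueError("need at least one miRNA")
    return alpha_family / n_mirna


def select_svs(
    svs: SurrogateVariableSet,
    ct: pd.DataFrame,
    A: RelationshipMatrix,
    alpha_family: float = 0.05,
    covariates: pd.DataFrame | None = None,
) -> SurrogateVariableSet:
    """Flag SVs associated with at least one miRNA at Bonferroni.

    Each SV is tested against every miRNA row of ``ct`` (Ct values, NaN for
    non-detection) with the adaptive two-part test, the SV playing the
    predictor role.  An SV is selected iff its minimum p across miRNAs is
    below ``alpha_family / n_miRNA``.
    """
    if ct.shape[0] == 0:
        raise ValueError("empty miRNA set")
    thresh = sv_bonferroni_threshold(alpha_family, ct.shape[0])
    flags = {}
    min_ps = {}
    for sv_name in svs.sv_matrix.columns:
        sv_vec = svs.sv_matrix[sv_name]
        res = scan_two_part(ct, sv_vec, covariates, A, trait_id=sv_name)
        ps = [r.p for r in res if r.testable and r.p is not None]
        mp = float(min(ps)) if ps else np.nan
        min_ps[sv_name] = mp
        flags[sv_name] = bool(mp < thresh) if ps else False
    return SurrogateVariableSet(
        svs.sv_matrix,
        selected_flags=pd.Series(flags),
        min_p=pd.Series(min_ps),
        selection_alpha=alpha_family,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_covariates(
    pheno: pd.DataFrame,
    columns: list[str],
    imputed_cells: pd.DataFrame | None = None,
    svs: SurrogateVariableSet | None = None,
) -> pd.DataFrame:
    """Build the final covariate table for the models.

    Measured columns come from ``pheno``; imputed cell counts fill in only
    the cell types without a measured column (measured overrides imputed);
    selected SVs are appended.  Raises if any missing values remain.
    """
    out = pheno[columns].copy()
    if imputed_cells is not None:
        for cell in imputed_cells.columns:
            if cell not in out.columns:
                out[cell] = imputed_cells[cell].reindex(out.index)
    if svs is not None:
        sel = svs.selected().reindex(out.index)
        # drop SVs numerically spanned by the design so far: they carry no
        # adjustment information and would make the model singular
        base = np.column_stack([np.ones(len(out))] +
                               [out[c].to_numpy(dtype=float) for c in out])
        for c in sel.columns:
            v = sel[c].to_numpy(dtype=float)
            resid = v - base @ np.linalg.lstsq(base, v, rcond=None)[0]
            if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(v), 1.0):
                continue
            out[c] = sel[c]
            base = np.column_stack([base, v])
    if out.isna().any().any():
        bad = [c for c in out.columns if out[c].isna().any()]
        raise ValueError(f"covariate columns contain missing values: {bad}")
    if out.columns.duplicated().any():
        raise ValueError("duplicate covariate column names")
    return out
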