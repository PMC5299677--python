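"""Association scans: kinship linear mixed models, the adaptive two-part
test for detection-limited Ct data, per-trait BH FDR, and the
pedigree-preserving discovery/validation split.

Model
-----
For a continuous response y (log2 mRNA intensity, or Ct among detected
samples) with fixed-effect design X and additive relationship matrix A:

    y = X b + g + e,   g ~ N(0, sigma_g2 * A),   e ~ N(0, sigma_e2 * I)

Fitting uses a one-time eigendecomposition A = U D U'.  In the rotated
basis the covariance is diagonal, so REML reduces to a 1-D profile
optimization over the variance ratio lambda = sigma_g2 / sigma_e2.  The
trait test is the Wald chi-square (b/se)^2 of the trait coefficient against
a 1-df chi-square (equivalently z^2 against the normal).

The two-part test for semi-continuous Ct data is adaptive in the detection
rate d (fraction of samples with the miRNA detected, i.e. Ct below the
detection limit): d >= 0.90 uses the linear-branch (kinship LMM on detected
Ct values) p value alone; d < 0.10 uses the logistic branch (ordinary
logistic regression of the detection indicator) alone; in between the two
Wald chi-squares are summed and referred to a 2-df chi-square, whose upper
tail is exp(-x/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .pedigree import Pedigree, RelationshipMatrix

__all__ = [
    "EigenA",
    "LmmFit",
    "AssociationResult",
    "SplitAssignment",
    "fit_kinship_lmm",
    "scan_continuous",
    "two_part_test",
    "chi2_2df_sf",
    "bh_fdr",
    "split_discovery_validation",
]


# ---------------------------------------------------------------------------
# kinship LMM
# ---------------------------------------------------------------------------

@dataclass
class EigenA:
    """Cached eigendecomposition of a relationship matrix.

    Shared across all transcripts of a scan; the decomposition is the only
    O(n^3) step so it is done once per (cohort, sample-subset).
    """

    sample_order: list[str]
    eigvals: np.ndarray      # D, clipped at 0 (A is PSD up to roundoff)
    eigvecs: np.ndarray      # U

    @classmethod
    def from_matrix(cls, A: RelationshipMatrix) -> "EigenA":
        d, U = np.linalg.eigh(A.values)
        return cls(list(A.sample_order), np.clip(d, 0.0, None), U)

    @property
    def n(self) -> int:
        return len(self.sample_order)

    def rotate(self, arr: np.ndarray) -> np.ndarray:
        """U' @ arr for a vector or (n, k) matrix."""
        return self.eigvecs.T @ arr


@dataclass
class LmmFit:
    """REML (or fixed-variance GLS) fit of the kinship LMM for one response."""

    beta: float              # trait coefficient, response units per predictor unit
    se: float
    sigma_g2: float
    sigma_e2: float
    wald_chi2: float
    p: float
    reml_loglik: float
    beta_all: np.ndarray = field(default=None, repr=False)  # all fixed effects


def _reml_profile(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray, lam: float):
    """Profiled REML pieces at variance ratio lam = sigma_g2/sigma_e2.

    Returns (neg2_reml, beta_hat, sigma_e2_hat, XtWX_inv).
    """
    n, p = Xt.shape
    w = lam * d + 1.0                       # V = sigma_e2 * diag(w)
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    sigma_e2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    neg2 = ((n - p) * np.log(sigma_e2) + np.log(w).sum() + logdet_xx + (n - p))
    return neg2, beta, sigma_e2, XtWX


def fit_kinship_lmm(
    y: np.ndarray,
    X: np.ndarray,
    A: RelationshipMatrix | EigenA,
    trait_col: int = -1,
    var_components: tuple[float, float] | None = None,
) -> LmmFit:
    """Fit y = X b + g + e with g ~ N(0, sigma_g2 A), e ~ N(0, sigma_e2 I).

    Parameters
    ----------
    y, X
        Response vector and full-rank design (including intercept), aligned
        with ``A``'s sample order.
    A
        Relationship matrix or its cached eigendecomposition.
    trait_col
        Column of X whose Wald test is reported (default: last).
    var_components
        Optional ``(sigma_g2, sigma_e2)``: skip REML and do GLS at these
        known variances (used e.g. by oracle comparisons).

    Raises
    ------
    ValueError
        If X is singular (collinear columns are named) or y is constant.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different sample counts")
    if n <= p + 2:
        raise ValueError(f"too few samples (n={n}) for {p} fixed effects")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [int(j) for j in range(p) if abs(r[min(j, p - 1), j]) < 1e-10]
        raise ValueError(f"design matrix singular; suspect columns {bad}")

    eig = A if isinstance(A, EigenA) else EigenA.from_matrix(A)
    if eig.n != n:
        raise ValueError("A and data have different sample counts")
    d = eig.eigvals
    yt = eig.rotate(y)
    Xt = eig.rotate(X)

    if var_components is not None:
        sg2, se2 = var_components
        w = sg2 * d + se2
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        cov = np.linalg.inv(XtWX)
        lam = sg2 / se2 if se2 > 0 else np.inf
        neg2 = _reml_profile(d, yt, Xt, lam)[0] if np.isfinite(lam) else np.nan
        ll = -0.5 * neg2 if np.isfinite(neg2) else np.nan
    else:
        # profile REML over log-lambda, with the lambda=0 boundary checked
        def obj(loglam: float) -> float:
            return _reml_profile(d, yt, Xt, np.exp(loglam))[0]

        res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        neg2_0, *_ = _reml_profile(d, yt, Xt, 0.0)
        if neg2_0 <= res.fun:
            lam = 0.0
            neg2 = neg2_0
        else:
            neg2 = res.fun
        _, beta, se2, XtWX = _reml_profile(d, yt, Xt, lam)
        sg2 = lam * se2
        cov = np.linalg.inv(XtWX) * se2
        ll = -0.5 * neg2

    b = float(beta[trait_col])
    se = float(np.sqrt(cov[trait_col, trait_col]))
    chi2 = (b / se) ** 2
    pval = float(stats.chi2.sf(chi2, df=1))
    return LmmFit(beta=b, se=se, sigma_g2=float(sg2), sigma_e2=float(se2),
                  wald_chi2=float(chi2), p=max(pval, 5e-324),
                  reml_loglik=float(ll), beta_all=np.asarray(beta))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

Branch = Literal["linear", "logistic", "combined", "lmm"]


@dataclass
class AssociationResult:
    """One transcript x trait association."""

    transcript_id: str
    trait_id: str
    branch: Branch
    detection_rate: float
    beta: float                  # linear-branch (or LMM) effect
    se: float
    beta_logistic: float | None
    chi2: float
    p: float | None
    q: float | None = None
    testable: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "trait_id": self.trait_id,
            "branch": self.branch,
            "detection_rate": self.detection_rate,
            "beta": self.beta,
            "se": self.se,
            "beta_logistic": self.beta_logistic,
            "chi2": self.chi2,
            "p": self.p,
            "q": self.q,
            "testable": self.testable,
            "note": self.note,
        }


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# continuous (mRNA) scan
# ---------------------------------------------------------------------------

def _design(trait: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    n = trait.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        cols.extend(np.asarray(covariates[c], dtype=float) for c in covariates)
    cols.append(np.asarray(trait, dtype=float))
    return np.column_stack(cols)


def scan_continuous(
    expr: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    A: RelationshipMatrix | EigenA,
    trait_id: str | None = None,
) -> list[AssociationResult]:
    """Kinship-LMM scan of every transcript (rows of ``expr``) on one trait.

    ``expr`` is transcripts x samples; the trait and covariates are indexed
    by sample.  A is eigendecomposed once and reused; the whole expression
    matrix is rotated in a single matrix product.
    """
    samples = list(expr.columns)
    eig = A if isinstance(A, EigenA) else EigenA.from_matrix(A)
    if eig.sample_order != samples:
        if set(eig.sample_order) != set(samples):
            raise ValueError("expression and A cover different samples")
        raise ValueError("expression columns and A sample order differ; align first")
    trait = trait.loc[samples]
    if covariates is not None:
        covariates = covariates.loc[samples]
    X = _design(trait.to_numpy(dtype=float), covariates)
    trait_id = trait_id or (trait.name if trait.name else "trait")

    d = eig.eigvals
    Xt = eig.rotate(X)
    Yt = eig.rotate(expr.to_numpy(dtype=float).T)   # n x G rotated responses

    out: list[AssociationResult] = []
    cache: dict[bytes, LmmFit] = {}
    for gi, tid in enumerate(expr.index):
        yt = Yt[:, gi]
        key = yt.tobytes()
        fit = cache.get(key)
        if fit is None:
            fit = _fit_rotated(d, yt, Xt)
            cache[key] = fit
        out.append(AssociationResult(
            transcript_id=str(tid), trait_id=str(trait_id), branch="lmm",
            detection_rate=1.0, beta=fit.beta, se=fit.se, beta_logistic=None,
            chi2=fit.wald_chi2, p=fit.p))
    return out


_TINY_P = 5e-324  # smallest subnormal double; keeps p in (0, 1] for BH


def _fit_rotated(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> LmmFit:
    """REML fit when the rotation has already been applied."""
    def obj(loglam: float) -> float:
        return _reml_profile(d, yt, Xt, np.exp(loglam))[0]

    res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    neg2_0, *_ = _reml_profile(d, yt, Xt, 0.0)
    if neg2_0 <= res.fun:
        lam, neg2 = 0.0, neg2_0
    else:
        neg2 = res.fun
    _, beta, se2, XtWX = _reml_profile(d, yt, Xt, lam)
    cov = np.linalg.inv(XtWX) * se2
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    chi2 = (b / se) ** 2
    return LmmFit(beta=b, se=se, sigma_g2=lam * se2, sigma_e2=se2,
                  wald_chi2=chi2, p=max(float(stats.chi2.sf(chi2, df=1)), _TINY_P),
                  reml_loglik=-0.5 * neg2, beta_all=np.asarray(beta))


# ---------------------------------------------------------------------------
# two-part test
# ---------------------------------------------------------------------------

def chi2_2df_sf(x: float) -> float:
    """Upper tail of the 2-df chi-square: exp(-x/2) in closed form."""
    return float(np.exp(-x / 2.0))


def two_part_test(
    ct_row: pd.Series,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    A: RelationshipMatrix,
    threshold_high: float = 0.90,
    threshold_low: float = 0.10,
    transcript_id: str | None = None,
    trait_id: str | None = None,
    eig_cache: dict | None = None,
) -> AssociationResult:
    """Adaptive two-part association test for one miRNA's Ct values.

    ``ct_row`` holds Ct values with NaN marking non-detection.  Branching on
    the detection rate d: d >= threshold_high -> linear branch only;
    d < threshold_low -> logistic branch only; otherwise the two Wald
    chi-squares are summed against a 2-df chi-square.
    """
    samples = list(ct_row.index)
    trait = trait.loc[samples]
    cov = covariates.loc[samples] if covariates is not None else None
    tid = transcript_id or (str(ct_row.name) if ct_row.name is not None else "miRNA")
    trait_id = trait_id or (str(trait.name) if trait.name is not None else "trait")

    detected = ct_row.notna().to_numpy()
    d_rate = float(detected.mean())
    X_full = _design(trait.to_numpy(dtype=float), cov)

    branch: Branch
    if d_rate >= threshold_high:
        branch = "linear"
    elif d_rate < threshold_low:
        branch = "logistic"
    else:
        branch = "combined"

    lin_fit: LmmFit | None = None
    lin_note = ""
    if branch in ("linear", "combined"):
        idx = np.flatnonzero(detected)
        if idx.size < X_full.shape[1] + 3:
            lin_note = "linear branch untestable: too few detected samples"
        else:
            sub_ids = [samples[i] for i in idx]
            key = tuple(sub_ids)
            if eig_cache is not None and key in eig_cache:
                eig = eig_cache[key]
            else:
                eig = EigenA.from_matrix(A.subset(sub_ids))
                if eig_cache is not None:
                    eig_cache[key] = eig
            try:
                lin_fit = fit_kinship_lmm(ct_row.to_numpy(dtype=float)[idx],
                                          X_full[idx], eig)
            except ValueError as exc:
                lin_note = f"linear branch failed: {exc}"

    logit_chi2 = None
    logit_beta = None
    logit_p = None
    logit_note = ""
    if branch in ("logistic", "combined"):
        yb = detected.astype(float)
        if yb.min() == yb.max():
            logit_note = "logistic branch untestable: detection is constant"
        else:
            try:
                with np.errstate(all="ignore"):
                    fit = Logit(yb, X_full).fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", False):
                    logit_note = "logistic model did not converge"
                else:
                    logit_beta = float(fit.params[-1])
                    z = logit_beta / float(fit.bse[-1])
                    if not np.isfinite(z):
                        logit_note = "logistic Wald statistic not finite"
                    else:
                        logit_chi2 = z * z
                        logit_p = max(float(stats.chi2.sf(logit_chi2, df=1)), _TINY_P)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                logit_note = f"logistic branch failed: {type(exc).__name__}"

    note = "; ".join(s for s in (lin_note, logit_note) if s)

    if branch == "linear":
        if lin_fit is None:
            return AssociationResult(tid, trait_id, branch, d_rate, np.nan,
                                     np.nan, None, np.nan, None,
                                     testable=False, note=note)
        return AssociationResult(tid, trait_id, branch, d_rate, lin_fit.beta,
                                 lin_fit.se, None, lin_fit.wald_chi2,
                                 lin_fit.p, note=note)
    if branch == "logistic":
        if logit_chi2 is None:
            return AssociationResult(tid, trait_id, branch, d_rate, np.nan,
                                     np.nan, None, np.nan, None,
                                     testable=False, note=note)
        return AssociationResult(tid, trait_id, branch, d_rate, np.nan,
                                 np.nan, logit_beta, logit_chi2, logit_p,
                                 note=note)
    # combined: both parts must be testable, else fall back to whichever is
    if lin_fit is None and logit_chi2 is None:
        return AssociationResult(tid, trait_id, branch, d_rate, np.nan, np.nan,
                                 None, np.nan, None, testable=False, note=note)
    if lin_fit is None or logit_chi2 is None:
        return AssociationResult(tid, trait_id, branch, d_rate,
                                 lin_fit.beta if lin_fit else np.nan,
                                 lin_fit.se if lin_fit else np.nan,
                                 logit_beta,
                                 np.nan, None, testable=False, note=note)
    chi2 = lin_fit.wald_chi2 + logit_chi2
    return AssociationResult(tid, trait_id, branch, d_rate, lin_fit.beta,
                             lin_fit.se, logit_beta, chi2,
                             max(chi2_2df_sf(chi2), _TINY_P), note=note)


def scan_two_part(
    ct: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    A: RelationshipMatrix,
    threshold_high: float = 0.90,
    threshold_low: float = 0.10,
    trait_id: str | None = None,
) -> list[AssociationResult]:
    """Two-part test across all miRNAs (rows of ``ct``), sharing sub-A
    eigendecompositions between miRNAs with identical detection patterns."""
    cache: dict = {}
    return [
        two_part_test(ct.loc[m], trait, covariates, A,
                      threshold_high=threshold_high, threshold_low=threshold_low,
                      transcript_id=str(m), trait_id=trait_id, eig_cache=cache)
        for m in ct.index
    ]


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, within: Sequence | None = None):
    """Benjamini-Hochberg step-up q-values, optionally within groups.

    ``pvalues`` may contain NaN (untestable results); those entries are
    excluded from the correction and returned as NaN.  With ``within``,
    the correction is applied separately inside each group label (the
    pipeline uses trait x transcript-class groups).
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] <= 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    if within is None:
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return q
    within = np.asarray(within)
    for g in pd.unique(within):
        m = ok & (within == g)
        if m.any():
            q[m] = multipletests(p[m], method="fdr_bh")[1]
    return q


def attach_fdr(results: list[AssociationResult],
               by_trait: bool = True) -> list[AssociationResult]:
    """Fill the ``q`` field in place (BH within trait when ``by_trait``)."""
    p = [r.p if (r.p is not None and r.testable) else np.nan for r in results]
    groups = [r.trait_id for r in results] if by_trait else None
    q = bh_fdr(p, within=groups)
    for r, qi in zip(results, q):
        r.q = None if np.isnan(qi) else float(qi)
    return results


# ---------------------------------------------------------------------------
# discovery / validation split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Family-preserving partition of the cohort into discovery/validation."""

    family_sets: dict[str, str]           # family_id -> {discovery, validation}
    sample_sets: dict[str, str]           # individual_id -> set label

    def samples(self, label: str) -> list[str]:
        return [s for s, l in self.sample_sets.items() if l == label]


def split_discovery_validation(ped: Pedigree, seed: int) -> SplitAssignment:
    """Random equal split that keeps every family intact.

    Families are shuffled by the seed then assigned greedily to whichever
    set is currently smaller, so the final imbalance never exceeds the
    largest family size.
    """
    rng = np.random.default_rng(seed)
    fams = ped.families()
    names = list(fams)
    rng.shuffle(names)
    sizes = {"discovery": 0, "validation": 0}
    fam_sets: dict[str, str] = {}
    for fam in names:
        label = "discovery" if sizes["discovery"] <= sizes["validation"] else "validation"
        fam_sets[fam] = label
        sizes[label] += len(fams[fam])
    sample_sets = {iid: fam_sets[r.family_id]
                   for iid, r in zip(ped.individual_ids, ped.records)}
    return SplitAssignment(fam_sets, sample_sets)
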