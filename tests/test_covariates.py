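"""PLS cell-count imputation and surrogate-variable estimation/selection."""

import numpy as np
import pandas as pd
import pytest

from pedscan.covariates import (assemble_covariates, estimate_svs,
                                impute_cell_counts, select_svs,
                                sv_bonferroni_threshold)
from pedscan.pedigree import RelationshipMatrix


def expr_frame(X, prefix="G"):
    """samples x genes array -> genes x samples DataFrame."""
    n, g = X.shape
    return pd.DataFrame(X.T, index=[f"{prefix}{j}" for j in range(g)],
                        columns=[f"s{i}" for i in range(n)])


class TestImputeCellCounts:
    def test_noiseless_linear_combination_near_perfect(self, rng):
        """A cell count that is exactly a linear combination of 5 genes is
        recovered with cv accuracy > 0.99."""
        n, g = 300, 50
        X = rng.standard_normal((n, g))
        w = np.zeros(g)
        w[:5] = [1.0, -2.0, 0.5, 1.5, -1.0]
        counts = pd.DataFrame({"lymph": X @ w},
                              index=[f"s{i}" for i in range(n)])
        imputed, acc = impute_cell_counts(expr_frame(X), counts,
                                          n_components=5, n_folds=5)
        assert acc["lymph"] > 0.99
        assert imputed.shape == (n, 1)

    def test_permuted_labels_no_accuracy(self, rng):
        """Permutation-null oracle: shuffled labels give |accuracy| < 0.15."""
        n, g = 200, 40
        X = rng.standard_normal((n, g))
        y = X @ np.concatenate([np.ones(5), np.zeros(g - 5)])
        y_perm = rng.permutation(y)
        counts = pd.DataFrame({"mono": y_perm},
                              index=[f"s{i}" for i in range(n)])
        _, acc = impute_cell_counts(expr_frame(X), counts, n_components=5,
                                    n_folds=5, seed=1)
        assert abs(acc["mono"]) < 0.15

    def test_zero_variance_cell_type_named(self, rng):
        X = rng.standard_normal((150, 20))
        counts = pd.DataFrame({"baso": np.ones(150)},
                              index=[f"s{i}" for i in range(150)])
        with pytest.raises(ValueError, match="baso"):
            impute_cell_counts(expr_frame(X), counts, n_components=2)

    def test_too_many_components_rejected(self, rng):
        X = rng.standard_normal((120, 20))
        counts = pd.DataFrame({"eos": rng.standard_normal(120)},
                              index=[f"s{i}" for i in range(120)])
        with pytest.raises(ValueError):
            impute_cell_counts(expr_frame(X), counts, n_components=50)

    def test_gene_order_invariance(self, rng):
        n, g = 200, 30
        X = rng.standard_normal((n, g))
        counts = pd.DataFrame({"wbc": X[:, 0] + 0.5 * X[:, 1]},
                              index=[f"s{i}" for i in range(n)])
        e = expr_frame(X)
        imp1, acc1 = impute_cell_counts(e, counts, n_components=3, seed=3)
        perm = list(np.random.default_rng(1).permutation(e.index))
        imp2, acc2 = impute_cell_counts(e.loc[perm], counts, n_components=3,
                                        seed=3)
        assert acc1["wbc"] == pytest.approx(acc2["wbc"], abs=1e-8)
        np.testing.assert_allclose(imp1.to_numpy(), imp2.to_numpy(), atol=1e-8)


class TestEstimateSvs:
    def test_fixed_k_orthonormal(self, rng):
        n, g = 100, 200
        X = rng.standard_normal((n, g))
        M = np.ones((n, 1))
        svs = estimate_svs(expr_frame(X), M, k=2)
        assert svs.k == 2
        sv = svs.sv_matrix.to_numpy()
        np.testing.assert_allclose(sv.T @ sv, np.eye(2), atol=1e-10)

    def test_k_too_large_rejected(self, rng):
        X = rng.standard_normal((30, 50))
        with pytest.raises(ValueError, match="exceeds"):
            estimate_svs(expr_frame(X), np.ones((30, 1)), k=40)

    def test_rank_deficient_model_matrix_rejected(self, rng):
        X = rng.standard_normal((40, 30))
        M = np.column_stack([np.ones(40), np.ones(40)])
        with pytest.raises(ValueError, match="rank"):
            estimate_svs(expr_frame(X), M, k=1)

    def test_auto_chooses_zero_under_null(self, rng):
        """Parallel analysis keeps no component on covariates + iid noise in
        at least 90% of seeded runs."""
        n, g = 100, 300
        zeros = 0
        runs = 25
        for s in range(runs):
            r = np.random.default_rng(1000 + s)
            M = np.column_stack([np.ones(n), r.standard_normal(n)])
            X = M @ r.standard_normal((2, g)) + r.standard_normal((n, g))
            svs = estimate_svs(expr_frame(X), M, k="auto", n_permutations=25,
                               seed=s)
            zeros += svs.k == 0
        assert zeros >= 0.9 * runs

    def test_planted_factor_recovered(self, rng):
        """One strong latent factor loading on 30% of transcripts: the first
        SV correlates with it at |r| > 0.9."""
        n, g = 150, 400
        factor = rng.standard_normal(n)
        load = np.zeros(g)
        idx = rng.choice(g, int(0.3 * g), replace=False)
        load[idx] = rng.normal(0, 2.0, idx.size)
        X = np.outer(factor, load) + rng.standard_normal((n, g))
        svs = estimate_svs(expr_frame(X), np.ones((n, 1)), k="auto",
                           n_permutations=25, seed=0)
        assert svs.k >= 1
        r = np.corrcoef(svs.sv_matrix["SV1"], factor)[0, 1]
        assert abs(r) > 0.9


class TestSelectSvs:
    def _panel(self, rng, n=150, n_mir=10):
        samples = [f"s{i}" for i in range(n)]
        A = RelationshipMatrix(samples, np.eye(n))
        ct = pd.DataFrame(rng.normal(24, 1, (n_mir, n)),
                          index=[f"miR-{j}" for j in range(n_mir)],
                          columns=samples)
        return samples, A, ct

    def test_sv_equal_to_mirna_selected(self, rng):
        samples, A, ct = self._panel(rng)
        v = ct.iloc[0].to_numpy(dtype=float).copy()
        v = (v - v.mean())
        v /= np.linalg.norm(v)
        svs = pd.DataFrame({"SV1": v}, index=samples)
        from pedscan.covariates import SurrogateVariableSet
        out = select_svs(SurrogateVariableSet(svs), ct, A, alpha_family=0.05)
        assert bool(out.selected_flags["SV1"])

    def test_alpha_zero_selects_nothing(self, rng):
        samples, A, ct = self._panel(rng)
        v = ct.iloc[0].to_numpy(dtype=float).copy()
        v /= np.linalg.norm(v)
        from pedscan.covariates import SurrogateVariableSet
        out = select_svs(SurrogateVariableSet(pd.DataFrame({"SV1": v},
                                                           index=samples)),
                         ct, A, alpha_family=0.0)
        assert not out.selected_flags.any()

    def test_empty_mirna_set_rejected(self, rng):
        samples, A, ct = self._panel(rng)
        from pedscan.covariates import SurrogateVariableSet
        v = pd.DataFrame({"SV1": np.ones(len(samples))}, index=samples)
        with pytest.raises(ValueError, match="empty"):
            select_svs(SurrogateVariableSet(v), ct.iloc[:0], A)

    def test_bonferroni_threshold_value(self):
        assert sv_bonferroni_threshold(0.05, 280) == pytest.approx(0.05 / 280)

    def test_null_svs_rarely_selected(self):
        """Family-wise calibration: pure-noise SVs against null miRNAs are
        selected at ~ the Bonferroni family rate (mean count <= 2 of 8)."""
        total = 0
        seeds = 12
        for s in range(seeds):
            r = np.random.default_rng(3000 + s)
            n, n_mir, n_sv = 200, 40, 8
            samples = [f"s{i}" for i in range(n)]
            A = RelationshipMatrix(samples, np.eye(n))
            ct = pd.DataFrame(r.normal(24, 1, (n_mir, n)),
                              index=[f"miR-{j}" for j in range(n_mir)],
                              columns=samples)
            sv_raw, _ = np.linalg.qr(r.standard_normal((n, n_sv)))
            from pedscan.covariates import SurrogateVariableSet
            svs = SurrogateVariableSet(pd.DataFrame(
                sv_raw, index=samples,
                columns=[f"SV{k+1}" for k in range(n_sv)]))
            out = select_svs(svs, ct, A, alpha_family=0.05)
            total += int(out.selected_flags.sum())
        # E[selected] ~ n_sv * (1 - (1-0.05/40)^40) ~ 0.4 per seed
        assert total / seeds <= 2.0


class TestAssembleCovariates:
    def test_measured_overrides_imputed_and_svs_append(self, rng):
        n = 20
        idx = [f"s{i}" for i in range(n)]
        pheno = pd.DataFrame({"age": rng.normal(50, 10, n),
                              "sex": rng.integers(0, 2, n).astype(float),
                              "lymph": rng.random(n)}, index=idx)
        imputed = pd.DataFrame({"lymph": np.zeros(n), "mono": rng.random(n)},
                               index=idx)
        out = assemble_covariates(pheno, ["age", "sex", "lymph"],
                                  imputed_cells=imputed)
        np.testing.assert_array_equal(out["lymph"], pheno["lymph"])  # measured wins
        assert "mono" in out.columns

    def test_missing_values_rejected(self):
        pheno = pd.DataFrame({"age": [50.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="age"):
            assemble_covariates(pheno, ["age"])


def test_projection_idempotence(small_cohort):
    """An SV already spanned by the model matrix is pruned at assembly, so
    downstream coefficient estimates are unchanged within 1e-8."""
    from pedscan.association import scan_continuous
    from pedscan.covariates import SurrogateVariableSet
    c = small_cohort
    cov0 = assemble_covariates(c.phenotypes, ["age", "sex"])
    redundant = 0.3 * c.phenotypes["age"] + 0.1 * c.phenotypes["sex"] + 5.0
    svs = SurrogateVariableSet(pd.DataFrame({"SVdup": redundant}))
    cov1 = assemble_covariates(c.phenotypes, ["age", "sex"], svs=svs)
    assert "SVdup" not in cov1.columns
    expr = c.mrna.iloc[:10]
    res0 = scan_continuous(expr, c.phenotypes["BMI"], cov0, c.relationship)
    res1 = scan_continuous(expr, c.phenotypes["BMI"], cov1, c.relationship)
    for a, b in zip(res0, res1):
        assert a.beta == pytest.approx(b.beta, abs=1e-8)
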