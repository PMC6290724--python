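import numpy as np
import pytest
from scipy import stats

from rsnconn.group_inference import (
    adjusted_group_ttest,
    compare_groups,
    demographics_table,
    fdr_bh,
    fisher_exact_2x2,
    mann_whitney_u,
    permutation_pvalues,
    residualize,
    welch_ttest,
)


def _glm_t_oracle(y, g, cov):
    """Group t by explicit normal equations (independent of GroupModel)."""
    n = len(y)
    X = np.column_stack([np.ones(n), cov, g]) if cov is not None else np.column_stack(
        [np.ones(n), g]
    )
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - X.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1])
    return beta[-1] / se


class TestResidualize:
    def test_orthogonal_covariate_gives_centered_measure(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        cov = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to trend? ensure below
        cov = cov - cov.mean()
        y_c = y - y.mean()
        cov = cov - (cov @ y_c) / (y_c @ y_c) * y_c  # force orthogonality
        r = residualize(y, cov)
        assert np.allclose(r, y - y.mean(), atol=1e-10)

    def test_perfect_fit_gives_zero_residuals(self):
        age = np.array([50.0, 60, 70, 55, 65])
        r = residualize(2 * age, age)
        assert np.allclose(r, 0, atol=1e-9)

    def test_matches_normal_equations(self, rng):
        y = rng.normal(size=10)
        cov = rng.normal(size=(10, 2))
        Z = np.column_stack([np.ones(10), cov])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert np.allclose(residualize(y, cov), y - Z @ beta, atol=1e-10)

    def test_rank_deficiency_is_error(self):
        y = np.arange(5.0)
        cov = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank"):
            residualize(y, cov)


class TestAdjustedGroupTTest:
    def test_identical_groups_give_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["patient"] * 3 + ["control"] * 3
        assert adjusted_group_ttest(vals, labels) == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_patients_minus_controls(self, rng):
        vals = np.concatenate([np.ones(3) + rng.normal(0, 1e-3, 3), np.zeros(3)])
        labels = ["patient"] * 3 + ["control"] * 3
        t = adjusted_group_ttest(vals, labels)
        assert t > 10

    def test_eight_subject_worked_example_vs_oracle(self, rng):
        y = rng.normal(size=8)
        g = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        cov = np.column_stack([rng.normal(size=8), rng.integers(0, 2, 8)])
        labels = ["patient" if v else "control" for v in g]
        assert adjusted_group_ttest(y, labels, cov) == pytest.approx(
            _glm_t_oracle(y, g, cov), abs=1e-10
        )

    def test_covariate_free_equals_pooled_t(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.4, 1, 9)
        labels = ["patient"] * 7 + ["control"] * 9
        t = adjusted_group_ttest(np.concatenate([a, b]), labels)
        ref = stats.ttest_ind(a, b, equal_var=True).statistic
        assert t == pytest.approx(ref, abs=1e-10)


class TestPermutationPvalues:
    def test_exhaustive_tiny_case_one_sided(self):
        # 4 subjects, values (0,0) vs (1,1): only 1 of the C(4,2)=6
        # assignments attains the observed patients-minus-controls extreme
        vals = np.array([1.0, 1.0, 0.0, 0.0])
        labels = ["patient", "patient", "control", "control"]
        _, p = permutation_pvalues(vals, labels, alternative="greater")
        assert p[0] == pytest.approx(1.0 / 6.0)
        _, p2 = permutation_pvalues(vals, labels, alternative="two-sided")
        assert p2[0] == pytest.approx(2.0 / 6.0)

    def test_exhaustive_is_seed_independent(self, rng):
        vals = rng.normal(size=8)
        labels = ["patient"] * 4 + ["control"] * 4
        _, p1 = permutation_pvalues(vals, labels, n_permutations=100, seed=1)
        _, p2 = permutation_pvalues(vals, labels, n_permutations=100, seed=999)
        assert np.array_equal(p1, p2)

    def test_constant_measure_p_one_with_warning(self):
        vals = np.full(8, 3.0)
        labels = ["patient"] * 4 + ["control"] * 4
        with pytest.warns(RuntimeWarning, match="constant"):
            t, p = permutation_pvalues(vals, labels)
        assert p[0] == 1.0 and t[0] == 0.0

    def test_sampled_agrees_with_exhaustive(self, rng):
        vals = rng.normal(size=(8, 3))
        labels = ["patient"] * 4 + ["control"] * 4
        _, p_ex = permutation_pvalues(vals, labels, n_permutations=70)
        _, p_s = permutation_pvalues(
            vals, labels, n_permutations=69, seed=5, p_convention="proportion"
        )
        # 69 < C(8,4)=70 forces sampling; proportions converge to the
        # exhaustive values, here checked at a loose Monte-Carlo tolerance
        _, p_big = permutation_pvalues(
            vals, labels, n_permutations=20000, seed=5, p_convention="proportion"
        )
        assert np.all(np.abs(p_big - p_ex) < 0.02)
        assert p_s.shape == (3,)

    def test_freedman_lane_null_p_approximately_uniform(self, rng):
        # 300 independent null studies with age/sex covariates; the
        # permutation p-values should be uniform (KS test, alpha=0.01)
        pvals = []
        n = 20
        labels = ["patient"] * 10 + ["control"] * 10
        for _ in range(300):
            y = rng.normal(size=n)
            cov = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)])
            _, p = permutation_pvalues(
                y, labels, covariates=cov, n_permutations=500, seed=int(rng.integers(2**31))
            )
            pvals.append(p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFDR:
    def test_step_up_thresholds(self):
        reject, p_adj = fdr_bh([0.01, 0.02, 0.03], alpha=0.05)
        assert reject.all()
        assert p_adj[-1] == pytest.approx(0.03)

    def test_all_ones_none_rejected(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_p(self):
        reject, _ = fdr_bh([0.04], alpha=0.05)
        assert reject.all()

    def test_empty_input(self):
        reject, p_adj = fdr_bh([])
        assert reject.size == 0 and p_adj.size == 0

    def test_superset_of_bonferroni(self, rng):
        p = rng.uniform(size=40) ** 2
        reject_fdr, _ = fdr_bh(p, alpha=0.05)
        bonf = p < 0.05 / p.size
        assert np.all(reject_fdr[bonf])

    def test_adjusted_p_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=25)
        _, p_adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[7, 8], [5, 10]], 0.7104),
            ([[6, 9], [3, 12]], 0.4270),
            ([[7, 8], [8, 7]], 1.0),  # reported as > 0.9999
            ([[2, 13], [3, 12]], 1.0),
            ([[1, 14], [2, 13]], 1.0),
        ],
    )
    def test_clinical_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=5e-5)

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(1, 15, size=(2, 2))
            ours = fisher_exact_2x2(t)
            ref = stats.fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_non_integer_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_clear_separation(self):
        t, df, p = welch_ttest([1.0, 2, 3], [11.0, 12, 13])
        assert abs(t) > 10 and p < 0.01

    def test_matches_hand_formula(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 2, 9)
        t, df, p = welch_ttest(a, b)
        va, vb = a.var(ddof=1) / 6, b.var(ddof=1) / 9
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 5 + vb**2 / 8)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-8)

    def test_both_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            welch_ttest([2.0, 2.0], [3.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 by enumeration of C(6,3)

    def test_single_tied_values(self):
        _, p = mann_whitney_u([5.0], [5.0])
        assert p == pytest.approx(1.0)

    def test_asymptotic_close_to_exact_at_boundary(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        _, p_ours = mann_whitney_u(a, b)  # exact path (n=12, no ties)
        p_approx = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(p_ours - p_approx) < 0.01


class TestCompareGroups:
    def test_families_and_flags(self, rng):
        import pandas as pd

        n = 16
        labels = ["patient"] * 8 + ["control"] * 8
        cols = [f"gamma_r{i}" for i in range(4)] + ["intra_AN", "inter_AN_SMN"]
        df = pd.DataFrame(rng.normal(size=(n, 6)), columns=cols)
        df["gamma_r0"] += np.array([2.0] * 8 + [0.0] * 8)  # planted effect
        cov = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)])
        res = compare_groups(df, labels, covariates=cov, n_permutations=500, seed=3)
        assert set(res["family"]) == {"nodal", "network"}
        assert (res["sig_unc"] == (res["p_perm"] < 0.05)).all()
        planted = res.set_index("measure").loc["gamma_r0"]
        assert planted["p_perm"] == res["p_perm"].min()


def test_demographics_table_layout(small_study):
    df = demographics_table(small_study.records)
    assert set(df["characteristic"]) >= {"age", "sex", "mmse", "moca", "mean_fd"}
    assert ((df["pvalue"] >= 0) & (df["pvalue"] <= 1)).all()
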