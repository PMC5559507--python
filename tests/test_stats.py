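import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from mspli import (
    build_initiation_score,
    cronbach_alpha,
    edge_spearman,
    lilliefors_test,
    median_split_roc,
    permutation_correct,
    residualize,
    sqrt_transform_aes,
)


class TestSqrtTransform:
    def test_values(self):
        np.testing.assert_array_equal(
            sqrt_transform_aes(np.array([25.0, 0.0, 4.0])), [5.0, 0.0, 2.0]
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform_aes(np.array([-1.0]))

    def test_rank_preserving(self, rng):
        x = rng.uniform(18, 39, 50)
        assert np.array_equal(
            ss.rankdata(x), ss.rankdata(sqrt_transform_aes(x))
        )


class TestLilliefors:
    def test_null_calibration(self):
        # p should be ~uniform for normal samples: 5% rejections at alpha=.05
        rejections = 0
        runs = 200
        for i in range(runs):
            x = np.random.default_rng(i).standard_normal(500)
            _, p = lilliefors_test(x)
            rejections += p < 0.05
        assert abs(rejections / runs - 0.05) < 0.05

    def test_power_against_uniform(self):
        hits = 0
        runs = 50
        for i in range(runs):
            x = np.random.default_rng(i).uniform(0, 1, 500)
            _, p = lilliefors_test(x)
            hits += p < 0.01
        assert hits / runs > 0.95

    def test_monte_carlo_agrees_with_table(self):
        x = np.random.default_rng(3).standard_normal(100)
        s_t, p_t = lilliefors_test(x, method="table")
        s_m, p_m = lilliefors_test(x, method="mc")
        assert s_t == pytest.approx(s_m, abs=1e-12)
        assert p_m == pytest.approx(p_t, abs=0.08)

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_test(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            lilliefors_test(np.full(20, 3.0))


class TestInitiationComposite:
    def _cohort(self, items):
        df = pd.DataFrame(items)
        return df

    def test_identical_items_alpha_one(self):
        x = np.random.default_rng(0).standard_normal(30)
        items = np.column_stack([x, x, x])
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_alpha_zero(self):
        # sum of item variances equals total variance when uncorrelated;
        # construct exactly uncorrelated columns via QR
        rng = np.random.default_rng(1)
        base = np.column_stack([np.ones(40), rng.standard_normal((40, 5))])
        q, _ = np.linalg.qr(base)
        items = q[:, 1:]  # centered (orthogonal to 1) and mutually orthogonal
        items = items / items.std(axis=0, ddof=1)
        assert cronbach_alpha(items) == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        items = rng.standard_normal((25, 4)) + rng.standard_normal((25, 1))
        ours = cronbach_alpha(items)
        theirs = pg.cronbach_alpha(data=pd.DataFrame(items))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_double_reversal_is_identity(self, rng):
        cols = {
            "phonemic_fluency": rng.standard_normal(20),
            "semantic_fluency": rng.standard_normal(20),
            "five_point": rng.standard_normal(20),
            "tmt_a": rng.standard_normal(20),
            "stroop_naming": rng.standard_normal(20),
        }
        df = pd.DataFrame(cols)
        flags = {k: False for k in cols}
        a = build_initiation_score(df, flags).initiation
        # negating a column and flagging it reversed is the identity
        df2 = df.copy()
        df2["tmt_a"] = -df2["tmt_a"]
        flags2 = dict(flags, tmt_a=True)
        b = build_initiation_score(df2, flags2)
        np.testing.assert_allclose(a, b.initiation, atol=1e-12)
        assert build_initiation_score(df, flags).cronbach_alpha == pytest.approx(
            b.cronbach_alpha
        )

    def test_zero_variance_item_rejected(self):
        df = pd.DataFrame(
            {"phonemic_fluency": np.ones(10), "semantic_fluency": np.arange(10.0),
             "five_point": np.arange(10.0), "tmt_a": np.arange(10.0),
             "stroop_naming": np.arange(10.0)}
        )
        with pytest.raises(ValueError, match="zero variance"):
            build_initiation_score(df)


class TestResidualize:
    def _confounds(self, rng, n=30):
        return pd.DataFrame(
            {
                "age": rng.uniform(50, 80, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "education": rng.uniform(8, 20, n),
                "MMS": rng.uniform(25, 30, n),
                "LED": rng.uniform(100, 1200, n),
            }
        )

    def test_exact_linear_dependence_gives_zero_residuals(self, rng):
        conf = self._confounds(rng)
        values = np.exp(0.01 * conf["age"].to_numpy())[:, None]
        resid = residualize(values, conf, log_transform=True)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self, rng):
        conf = self._confounds(rng)
        values = np.abs(rng.normal(0.2, 0.05, (30, 8)))
        resid = residualize(values, conf, log_transform=True)
        X = conf.to_numpy()
        Xc = X - X.mean(axis=0)
        assert np.abs(Xc.T @ resid).max() < 1e-8

    def test_orthogonal_confounds_leave_centered_values(self, rng):
        conf = self._confounds(rng)
        X = np.column_stack([np.ones(30), conf.to_numpy()])
        q, _ = np.linalg.qr(X, mode="complete")
        values = q[:, [7]]  # orthogonal to the confound column space
        resid = residualize(values, conf, log_transform=False)
        np.testing.assert_allclose(resid, values - values.mean(), atol=1e-10)

    def test_collinear_confounds_named(self, rng):
        conf = self._confounds(rng)
        conf["LED"] = 2.0 * conf["age"] + 1.0
        with pytest.raises(ValueError) as err:
            residualize(np.ones((30, 2)) * 0.5, conf)
        assert "age" in str(err.value) or "LED" in str(err.value)

    def test_too_few_subjects_rejected(self, rng):
        conf = self._confounds(rng, n=6)
        with pytest.raises(ValueError, match="subjects"):
            residualize(np.full((6, 2), 0.5), conf)

    def test_nonpositive_values_rejected_for_log(self, rng):
        conf = self._confounds(rng)
        with pytest.raises(ValueError, match="positive"):
            residualize(np.zeros((30, 1)), conf, log_transform=True)

    def test_agrees_with_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        conf = self._confounds(rng)
        values = np.abs(rng.normal(0.2, 0.05, (30, 3)))
        resid = residualize(values, conf, log_transform=True)
        X = sm.add_constant(conf.to_numpy())
        for e in range(3):
            ref = sm.OLS(np.log(values[:, e]), X).fit().resid
            np.testing.assert_allclose(resid[:, e], ref, atol=1e-10)


class TestEdgeSpearman:
    def test_perfect_monotone_pair(self):
        x = np.array([[1.0], [2.0], [5.0], [9.0], [20.0], [21.0]])
        rho, p = edge_spearman(x, np.array([1.0, 4.0, 9.0, 16.0, 25.0, 36.0]))
        assert rho[0] == pytest.approx(1.0)

    def test_agrees_with_scipy(self, rng):
        vals = rng.normal(size=(25, 6))
        outcome = rng.normal(size=25)
        rho, p = edge_spearman(vals, outcome)
        for e in range(6):
            ref = ss.spearmanr(vals[:, e], outcome)
            assert rho[e] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[e] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_ties_midranked_like_scipy(self, rng):
        vals = rng.integers(0, 4, size=(30, 3)).astype(float)
        outcome = rng.integers(18, 40, size=30).astype(float)
        rho, _ = edge_spearman(vals, outcome)
        for e in range(3):
            assert rho[e] == pytest.approx(
                ss.spearmanr(vals[:, e], outcome).statistic, abs=1e-12
            )

    def test_null_p_uniform(self):
        # uncorrected p ~ U(0,1) under independence
        ps = []
        for i in range(500):
            r = np.random.default_rng(i)
            rho, p = edge_spearman(r.normal(size=(20, 1)), r.normal(size=20))
            ps.append(p[0])
        # KS against uniform
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_monotone_transform_invariance(self, rng):
        vals = np.abs(rng.normal(0.2, 0.05, size=(20, 4)))
        outcome = rng.uniform(18, 39, 20)
        r1, _ = edge_spearman(vals, outcome)
        r2, _ = edge_spearman(np.log(vals), np.sqrt(outcome))
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_spearman(rng.normal(size=(10, 2)), np.full(10, 3.0))


class TestPermutationCorrect:
    def test_extreme_rank_formula(self, rng):
        # an edge beating every permutation maximum gets p = 1/(n_perm+1)
        n = 30
        outcome = np.arange(n, dtype=float)
        vals = np.column_stack([outcome + rng.normal(0, 1e-9, n), rng.normal(size=n)])
        p = permutation_correct(vals, outcome, n_perm=200, seed=0)
        assert p[0] == pytest.approx(1.0 / 201.0)

    def test_corrected_at_least_uncorrected(self, rng):
        vals = rng.normal(size=(25, 40))
        outcome = rng.normal(size=25)
        _, p_unc = edge_spearman(vals, outcome)
        p_corr = permutation_correct(vals, outcome, n_perm=2000, seed=1)
        assert np.all(p_corr >= p_unc - 0.02)

    def test_deterministic_given_seed(self, rng):
        vals = rng.normal(size=(20, 10))
        outcome = rng.normal(size=20)
        p1 = permutation_correct(vals, outcome, n_perm=300, seed=7)
        p2 = permutation_correct(vals, outcome, n_perm=300, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_correct(rng.normal(size=(10, 2)), rng.normal(size=10), n_perm=50)


class TestMedianSplitRoc:
    def test_perfect_separation(self):
        aes = np.array([20, 21, 22, 27, 28, 30], dtype=float)
        values = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        roc = median_split_roc(values, aes)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_four_subject_pair_oracle(self):
        # brute-force over all (pos, neg) pairs: all 4 ordered pairs concordant
        roc = median_split_roc(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([20.0, 22.0, 26.0, 30.0])
        )
        assert roc.auc == 1.0

    def test_chance_level_for_independent_marker(self):
        aucs = []
        for i in range(200):
            r = np.random.default_rng(i)
            aes = r.integers(18, 40, 20).astype(float)
            if (aes > 24.5).all() or (aes <= 24.5).all():
                continue
            aucs.append(median_split_roc(r.normal(size=20), aes).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            median_split_roc(np.arange(4.0), np.array([18.0, 19.0, 20.0, 21.0]))
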