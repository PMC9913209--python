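"""Clinical statistics, sparse Bayes LASSO fusion and the clinical model."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from tlradiomics import fusion
from tlradiomics.errors import DataError, EnumerationLimitError, SchemaError
from tlradiomics.evaluation import auc


class TestCohenKappa:
    def test_perfect_agreement(self):
        v = np.array(["a", "b", "a", "c"])
        assert fusion.cohen_kappa(v, v) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # agreement table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        r1 = ["+"] * 25 + ["-"] * 25
        r2 = ["+"] * 20 + ["-"] * 5 + ["+"] * 10 + ["-"] * 15
        assert fusion.cohen_kappa(r1, r2) == pytest.approx(0.4)

    def test_independent_readers_near_zero(self):
        rng = np.random.default_rng(0)
        r1 = rng.integers(0, 2, 10000)
        r2 = rng.integers(0, 2, 10000)
        assert abs(fusion.cohen_kappa(r1, r2)) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        r1 = rng.integers(0, 3, 200)
        r2 = np.where(rng.random(200) < 0.7, r1, rng.integers(0, 3, 200))
        assert fusion.cohen_kappa(r1, r2) == pytest.approx(
            cohen_kappa_score(r1, r2)
        )

    def test_undefined_when_both_constant(self):
        with pytest.warns(RuntimeWarning):
            k = fusion.cohen_kappa(np.zeros(5), np.zeros(5))
        assert np.isnan(k)


class TestPearsonChi2:
    def test_uniform_table(self):
        chi2, df, p = fusion.pearson_chi2_2xk([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_training_cohort_gender(self):
        _, _, p = fusion.pearson_chi2_2xk([[64, 65], [50, 89]])
        assert round(p, 4) == 0.0240

    def test_whole_validation_gender(self):
        _, _, p = fusion.pearson_chi2_2xk([[102, 201], [60, 210]])
        assert round(p, 4) == 0.0024

    def test_zero_marginal_rejected(self):
        with pytest.raises(DataError):
            fusion.pearson_chi2_2xk([[0, 0], [5, 5]])


class TestFisherExact:
    def test_hand_enumerated_value(self):
        # margins 10/10 both ways; p = 2 * (C(10,1)C(10,9) + C(10,0)C(10,10)) / C(20,10)
        from math import comb

        expected = 2 * (comb(10, 1) * comb(10, 9) + 1) / comb(20, 10)
        assert fusion.fisher_exact_2xk([[1, 9], [9, 1]]) == pytest.approx(expected)

    def test_identical_rows_p_one(self):
        assert fusion.fisher_exact_2xk([[4, 6], [4, 6]]) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0:
                continue
            assert fusion.fisher_exact_2xk(t) == pytest.approx(
                float(fisher_exact(t).pvalue)
            )

    def test_matches_r_oracle_on_2x3(self):
        """Cross-check the 2 x k enumeration against R's fisher.test."""
        table = [[2, 3, 1], [4, 0, 5]]
        r_code = (
            "cat(sprintf('%.15g', fisher.test(matrix(c(2,4,3,0,1,5), nrow=2))$p.value))"
        )
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=120)
        r_p = float(out.stdout.strip())
        assert fusion.fisher_exact_2xk(table) == pytest.approx(r_p, abs=1e-9)

    def test_agrees_with_chi2_on_large_balanced_table(self):
        t = [[530, 470], [470, 530]]  # all expected counts 500
        p_f = fusion.fisher_exact_2xk(t)
        _, _, p_c = fusion.pearson_chi2_2xk(t)
        assert abs(p_f - p_c) < 0.01

    def test_enumeration_limit(self):
        with pytest.raises(EnumerationLimitError):
            fusion.fisher_exact_2xk(np.full((2, 6), 3))


class TestWilcoxonRanksum:
    def test_exact_small_sample(self):
        _, p = fusion.wilcoxon_ranksum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        _, p = fusion.wilcoxon_ranksum([1, 2, 3], [3, 1, 2])
        assert p == 1.0

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50) + 1.0
            _, p = fusion.wilcoxon_ranksum(x, y)
            rejections += p < 0.05
        assert rejections / 100 > 0.8


def _table_to_cohort(counts, var):
    """counts: 2 x k array (rows LGN/LAC); expand into a cohort DataFrame."""
    levels = [f"L{j}" for j in range(np.shape(counts)[1])]
    rows = []
    for label, row in enumerate(counts):
        for level, c in zip(levels, row):
            rows.extend({var: level, "label": label} for _ in range(int(c)))
    return pd.DataFrame(rows)


class TestUnivariateScreen:
    def test_clinical_validation_margin_p(self):
        # margin irregular/regular: LGN (21, 16), LAC (52, 10) -> p = 0.0030
        df = _table_to_cohort([[21, 16], [52, 10]], "margin")
        rep = fusion.univariate_screen(df, variables=["margin"])
        row = rep.table.iloc[0]
        assert row["test"] == "pearson_chi2"
        assert round(row["p_value"], 4) == 0.0030

    def test_clinical_validation_lobulated_p(self):
        df = _table_to_cohort([[20, 17], [18, 44]], "lobulated")
        rep = fusion.univariate_screen(df, variables=["lobulated"])
        assert round(rep.table.iloc[0]["p_value"], 4) == 0.0133

    def test_small_counts_dispatch_to_fisher(self):
        df = _table_to_cohort([[2, 8], [1, 9]], "rare")
        rep = fusion.univariate_screen(df, variables=["rare"])
        assert rep.table.iloc[0]["test"] == "fisher_exact"

    def test_constant_variable_degenerate(self):
        df = _table_to_cohort([[5, 0], [5, 0]], "const")
        df["const"] = "same"
        rep = fusion.univariate_screen(df, variables=["const"])
        row = rep.table.iloc[0]
        assert row["degenerate"] and row["p_value"] == 1.0

    def test_independent_variable_rarely_significant(self):
        false_hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "noise": rng.standard_normal(5000),
                "label": rng.integers(0, 2, 5000),
            })
            rep = fusion.univariate_screen(df, variables=["noise"],
                                           continuous=("noise",))
            false_hits += bool(rep.table.iloc[0]["significant"])
        assert false_hits <= 2


class TestSparseBayesLasso:
    def test_recovers_planted_covariates(self):
        recovered, false_inclusions = 0, []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((1000, 10))
            beta = np.zeros(10)
            beta[:3] = [0.8, -0.6, 0.5]
            p = 1 / (1 + np.exp(-X @ beta))
            y = (rng.random(1000) < p).astype(float)
            m = fusion.fit_sparse_bayes_lasso(X, y)
            sel = set(m.selected)
            recovered += {"x0", "x1", "x2"} <= sel
            false_inclusions.append(len(sel - {"x0", "x1", "x2"}))
        assert recovered >= 4
        assert np.median(false_inclusions) <= 1

    def test_pure_noise_selects_nothing(self):
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((1000, 10))
            y = (rng.random(1000) < 0.5).astype(float)
            counts.append(len(fusion.fit_sparse_bayes_lasso(X, y).selected))
        assert np.median(counts) == 0

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 8))
        beta = np.array([1.0, -0.8, 0.6, 0.4, 0.2, 0, 0, 0])
        y = (rng.random(400) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        sizes = []
        for lam in (2.0, 4.0, 8.0, 16.0, 32.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sizes.append(len(fusion.fit_sparse_bayes_lasso(
                    X, y, prior_scale=lam).selected))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_covariate_order_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((500, 4)),
                         columns=["a", "b", "c", "d"])
        y = (rng.random(500) < 1 / (1 + np.exp(-2 * X["a"] + X["c"]))).astype(float)
        m1 = fusion.fit_sparse_bayes_lasso(X, y)
        m2 = fusion.fit_sparse_bayes_lasso(X[["d", "c", "b", "a"]], y)
        assert set(m1.selected) == set(m2.selected)
        for name in m1.selected:
            i, j = m1.selected.index(name), m2.selected.index(name)
            assert m1.coefficients[i] == pytest.approx(m2.coefficients[j], rel=1e-6)


class TestTlrmScore:
    def test_empty_model_gives_half(self):
        m = fusion.TlrmModel(selected=[], coefficients=np.zeros(0), intercept=0.0,
                             prior_scale=1.0, means={}, sds={})
        s = fusion.tlrm_score(m, pd.DataFrame({"x": [1, 2, 3]}))
        np.testing.assert_allclose(s, 0.5)

    def test_monotone_in_positive_coefficient(self):
        m = fusion.TlrmModel(selected=["age"], coefficients=np.array([1.0]),
                             intercept=0.0, prior_scale=1.0,
                             means={"age": 50.0}, sds={"age": 10.0})
        s = fusion.tlrm_score(m, pd.DataFrame({"age": [40, 50, 60, 70]}))
        assert np.all(np.diff(s) > 0)

    def test_missing_covariate_raises(self):
        m = fusion.TlrmModel(selected=["tls"], coefficients=np.array([1.0]),
                             intercept=0.0, prior_scale=1.0,
                             means={"tls": 0.5}, sds={"tls": 0.2})
        with pytest.raises(SchemaError):
            fusion.tlrm_score(m, pd.DataFrame({"age": [50]}))

    def test_separates_classes_on_synthetic_cohort(self):
        from tlradiomics import fixtures

        spec = fixtures.SyntheticCohortSpec(n=300, patch_size=32, seed=17)
        _, table = fixtures.generate_target_cohort(spec)
        y = table["label"].to_numpy()
        enc = fusion.encode_clinical(table)
        rng = np.random.default_rng(0)
        enc["tls"] = np.clip(0.5 + 0.25 * (y - 0.5) + 0.2 * rng.standard_normal(len(y)),
                             0, 1)
        cand = ["age", "nodule_size", "lobulated", "spiculated", "tls"]
        m = fusion.fit_sparse_bayes_lasso(enc[cand], y)
        scores = fusion.tlrm_score(m, enc)
        _, p = fusion.wilcoxon_ranksum(scores[y == 1], scores[y == 0])
        assert scores[y == 1].mean() > scores[y == 0].mean()
        assert p < 0.05


class TestClinicalLogistic:
    def _cohort(self, n, seed, beta=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "gender": rng.choice(["men", "women"], n),
            "age": rng.normal(57, 11, n),
            "lobulated": rng.choice(["absence", "presence"], n),
            "spiculated": rng.choice(["absence", "presence"], n),
        })
        enc = fusion.encode_clinical(df)
        if beta is None:
            beta = np.array([0.5, 0.04, 1.0, 0.8])
        lin = (enc[["gender", "age", "lobulated", "spiculated"]].to_numpy()
               @ beta - 0.04 * 57)
        df["label"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        return df, beta

    def test_label_leak_gives_training_auc_one(self):
        df, _ = self._cohort(100, 0)
        df["leak"] = df["label"].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fusion.fit_clinical_logistic(df, covariates=("leak",))
        scores = model.predict(fusion.encode_clinical(df))
        assert auc(scores, df["label"].to_numpy()) == 1.0

    def test_recovers_true_coefficients(self):
        df, beta = self._cohort(5000, 1)
        model = fusion.fit_clinical_logistic(df)
        for est, se, true in zip(model.coefficients, model.std_errors, beta):
            assert abs(est - true) < 3 * se

    def test_permuted_labels_training_auc_near_half(self):
        aucs = []
        for seed in range(20):
            df, _ = self._cohort(1000, 50 + seed)
            rng = np.random.default_rng(seed)
            df["label"] = rng.permutation(df["label"].to_numpy())
            if df["label"].nunique() < 2:
                continue
            model = fusion.fit_clinical_logistic(df)
            scores = model.predict(fusion.encode_clinical(df))
            aucs.append(auc(scores, df["label"].to_numpy()))
        assert all(0.45 <= a <= 0.60 for a in aucs)
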