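"""Mann-Whitney screening and the sparse Bayesian ELM signature."""

import warnings
from itertools import combinations

import numpy as np
import pytest

from tlradiomics import signature as sig
from tlradiomics.errors import DataError, SchemaError


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate all label assignments, ties as 1/2."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(mask):
        a = pooled[mask]
        b = pooled[~mask]
        d = a[:, None] - b[None, :]
        return (d > 0).sum() + 0.5 * (d == 0).sum()

    mean_u = n1 * len(y) / 2
    mask0 = np.zeros(len(pooled), dtype=bool)
    mask0[:n1] = True
    dev = abs(u_of(mask0) - mean_u)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n1):
        m = np.zeros(len(pooled), dtype=bool)
        m[list(comb)] = True
        total += 1
        if abs(u_of(m) - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_exact_small_sample_value(self):
        _, p = sig.mannwhitney_u([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_all_ties_p_one(self):
        _, p = sig.mannwhitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 6, rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 6, rng.integers(2, 6)).astype(float)
            _, p = sig.mannwhitney_u(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y))

    def test_matches_scipy_large_sample(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = rng.standard_normal(35) + 0.5
        u, p = sig.mannwhitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 0, 1
        _, p1 = sig.mannwhitney_filter(X, y)
        _, p2 = sig.mannwhitney_filter(np.exp(X), y)
        np.testing.assert_allclose(p1, p2)

    def test_screen_excludes_constant_feature(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = np.array([0] * 10 + [1] * 10)
        mask, p = sig.mannwhitney_filter(X, y)
        assert p[0] == 1.0 and not mask[0]
        assert mask[1]

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            sig.mannwhitney_filter(np.zeros((10, 2)), np.zeros(10))


def _planted(seed, n=200, d=51, beta=2.2):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    rng.shuffle(y)
    X = rng.standard_normal((n, d))
    X[:, 0] = y * beta + rng.standard_normal(n) * 0.8
    return X, y


class TestSbelm:
    def test_planted_feature_retained(self):
        X, y = _planted(0)
        m = sig.fit_sbelm(X, y)
        assert "f0" in m.retained_features
        assert m.converged

    def test_null_prunes_to_sparse_model(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 51))
        y = np.array([0] * 100 + [1] * 100)
        rng.shuffle(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sig.fit_sbelm(X, y)
        assert len(m.retained_features) <= 3

    def test_duplicate_column_leaves_scores_unchanged(self):
        X, y = _planted(7, d=20, beta=2.0)
        ids = [f"f{j}" for j in range(20)]
        pids = [f"p{i}" for i in range(len(y))]
        m1 = sig.fit_sbelm(X, y)
        s1 = sig.tls_score(m1, sig.FeatureMatrix(X, ids, pids))
        X2 = np.column_stack([X, X[:, 0]])
        m2 = sig.fit_sbelm(X2, y, feature_ids=ids + ["f0_dup"])
        s2 = sig.tls_score(m2, sig.FeatureMatrix(X2, ids + ["f0_dup"], pids))
        assert np.abs(s1 - s2).max() <= 1e-6

    def test_deterministic_and_serialisation_round_trip(self):
        X, y = _planted(3, d=10)
        m1 = sig.fit_sbelm(X, y)
        m2 = sig.fit_sbelm(X, y)
        assert m1.to_json() == m2.to_json()
        m3 = sig.SbelmModel.from_json(m1.to_json())
        pids = [f"p{i}" for i in range(len(y))]
        fm = sig.FeatureMatrix(X, [f"f{j}" for j in range(10)], pids)
        np.testing.assert_array_equal(sig.tls_score(m1, fm), sig.tls_score(m3, fm))

    def test_patient_order_invariance(self):
        X, y = _planted(4, d=10)
        m = sig.fit_sbelm(X, y)
        fm = sig.FeatureMatrix(X, [f"f{j}" for j in range(10)],
                               [f"p{i}" for i in range(len(y))])
        s = sig.tls_score(m, fm)
        perm = np.random.default_rng(0).permutation(len(y))
        fm_p = sig.FeatureMatrix(X[perm], fm.feature_ids,
                                 [fm.patient_ids[i] for i in perm])
        np.testing.assert_allclose(sig.tls_score(m, fm_p), s[perm])

    def test_hidden_layer_variant_fits_and_scores(self):
        X, y = _planted(8, d=10)
        cfg = sig.SbelmConfig(hidden="sigmoid", n_hidden=30, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sig.fit_sbelm(X, y, cfg)
        fm = sig.FeatureMatrix(X, [f"f{j}" for j in range(10)],
                               [f"p{i}" for i in range(len(y))])
        s = sig.tls_score(m, fm)
        assert np.all((s >= 0) & (s <= 1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            sig.fit_sbelm(np.zeros((5, 3)), np.array([0, 1, 0, 1, 0]))


class TestTlsScore:
    def test_zero_model_gives_half(self):
        m = sig.SbelmModel(
            retained_features=["f0"], weights=np.array([0.0]), intercept=0.0,
            ard_precisions={"f0": 1.0}, feature_means={"f0": 0.0},
            feature_sds={"f0": 1.0}, n_iter=1, converged=True, null_model=False,
        )
        s = sig.tls_score(m, np.zeros((4, 1)))
        np.testing.assert_allclose(s, 0.5)

    def test_monotone_in_positive_weight_feature(self):
        m = sig.SbelmModel(
            retained_features=["f0"], weights=np.array([1.5]), intercept=0.2,
            ard_precisions={"f0": 1.0}, feature_means={"f0": 0.0},
            feature_sds={"f0": 1.0}, n_iter=1, converged=True, null_model=False,
        )
        s = sig.tls_score(m, np.linspace(-3, 3, 10)[:, None])
        assert np.all(np.diff(s) > 0)

    def test_missing_feature_raises(self):
        m = sig.SbelmModel(
            retained_features=["f9"], weights=np.array([1.0]), intercept=0.0,
            ard_precisions={"f9": 1.0}, feature_means={"f9": 0.0},
            feature_sds={"f9": 1.0}, n_iter=1, converged=True, null_model=False,
        )
        fm = sig.FeatureMatrix(np.zeros((2, 1)), ["f0"], ["a", "b"])
        with pytest.raises(SchemaError):
            sig.tls_score(m, fm)

    def test_planted_simulation_test_auc(self):
        from tlradiomics.evaluation import auc

        X, y = _planted(11, n=400)
        m = sig.fit_sbelm(X[:200], y[:200])
        fm = sig.FeatureMatrix(X[200:], [f"f{j}" for j in range(X.shape[1])],
                               [f"p{i}" for i in range(200)])
        assert auc(sig.tls_score(m, fm), y[200:]) >= 0.9
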