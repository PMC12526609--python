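"""Mutual information, greedy mRMR and PCA thresholding oracles."""

import numpy as np
import pytest

import somnostage as ss
from somnostage.selection import (MiConfig, mrmr_rank, mutual_information,
                                  pca_fit, pca_transform, rank_pcs_mrmr,
                                  redundancy_batch,
                                  select_by_relevance_threshold,
                                  select_pcs_by_cumulative_variance)

#: Explained variances of the thirteen principal components of the
#: published single-night feature table (percent).
PUBLISHED_EXPLAINED_PCT = [16.9, 13.2, 12.2, 10.8, 8.7, 7.5, 6.6, 6.0,
                           4.9, 4.3, 3.8, 2.9, 2.2]


class TestMutualInformation:
    def test_identical_continuous_variable_gives_log2_bins(self, rng):
        a = rng.standard_normal(4000)
        mi = mutual_information(a, a, MiConfig(bins=4))
        assert mi == pytest.approx(2.0, abs=1e-9)   # H = log2(4)

    def test_perfectly_dependent_binary_pair_gives_one_bit(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 0, 1, 1])
        assert mutual_information(a, b) == pytest.approx(1.0)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(10_000), rng.random(10_000)
        assert mutual_information(a, b) <= 0.02

    def test_symmetry(self, rng):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 0.3 * a
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones(3), np.ones(4))


def _brute_force_mrmr(X, y, cfg=None):
    """Independent step-by-step greedy MIQ recomputation."""
    cfg = cfg or MiConfig()
    n = X.shape[1]
    rel = [mutual_information(X[:, j], y, cfg) for j in range(n)]
    order = [int(np.argmax(rel))]
    scores = [rel[order[0]]]
    while len(order) < n:
        best, best_score = None, -np.inf
        for j in range(n):
            if j in order:
                continue
            w = np.mean([mutual_information(X[:, j], X[:, s], cfg)
                         for s in order])
            miq = rel[j] / w if w > 0 else (np.inf if rel[j] > 0 else 0.0)
            if miq > best_score:
                best, best_score = j, miq
        order.append(best)
        scores.append(best_score)
    return order, scores


class TestMrmr:
    def test_single_feature_ranking(self, rng):
        y = rng.integers(0, 2, 200)
        X = (y + 0.1 * rng.standard_normal(200)).reshape(-1, 1)
        rk = mrmr_rank(X, y)
        assert len(rk) == 1
        assert rk.scores[0] == pytest.approx(rk.relevance["f0"])

    def test_duplicate_feature_ranks_below_independent_informative(self):
        rng = np.random.default_rng(2)
        n = 3000
        y = rng.integers(0, 2, n)
        f1 = y + 0.05 * rng.standard_normal(n)
        f2 = f1.copy()                      # exact copy: pure redundancy
        f3 = (y == 1) * rng.standard_normal(n) + y   # informative, different
        rk = mrmr_rank(np.column_stack([f1, f2, f3]), y,
                       feature_names=["f1", "f2", "f3"])
        assert rk.order[0] in ("f1", "f2")
        assert rk.order.index("f3") < rk.order.index("f2" if rk.order[0] == "f1"
                                                     else "f1")

    def test_greedy_trace_equals_brute_force_oracle(self, rng):
        n = 400
        y = rng.integers(0, 3, n)
        X = np.column_stack([
            y + rng.standard_normal(n),
            rng.standard_normal(n),
            0.5 * y + rng.standard_normal(n) * 0.5,
            rng.standard_normal(n) * 2,
            (y == 2).astype(float) + 0.3 * rng.standard_normal(n),
        ])
        rk = mrmr_rank(X, y)
        order, scores = _brute_force_mrmr(X, y)
        assert [f"f{j}" for j in order] == rk.order
        assert np.allclose(scores, rk.scores)

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            mrmr_rank(rng.standard_normal((50, 2)), np.zeros(50))

    def test_batch_redundancy_includes_self_terms(self, rng):
        X = rng.standard_normal((1000, 2))
        w = redundancy_batch(X)
        # two independent columns: W ≈ (H1 + H2)/4 dominated by self-MI
        h = mutual_information(X[:, 0], X[:, 0])
        assert w == pytest.approx(2 * h / 4, rel=0.15)


class TestRelevanceThreshold:
    def _ranking(self, scores):
        from somnostage.selection import MrmrRanking
        return MrmrRanking(order=[f"f{i}" for i in range(len(scores))],
                           scores=list(scores), relevance={}, redundancy=[])

    def test_threshold_filters_scores(self):
        kept = select_by_relevance_threshold(
            self._ranking([0.5, 0.011, 0.009]), 0.01)
        assert kept == ["f0", "f1"]

    def test_zero_threshold_keeps_all(self):
        kept = select_by_relevance_threshold(self._ranking([0.5, 0.0]), 0.0)
        assert len(kept) == 2

    def test_nothing_passing_warns(self):
        with pytest.warns(UserWarning):
            kept = select_by_relevance_threshold(
                self._ranking([0.001, 0.002]), 0.01)
        assert kept == []


class TestPca:
    def test_collinear_points_put_everything_on_pc1(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t])
        model = pca_fit(X, standardize=False)
        assert model.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50_000, 2))
        model = pca_fit(X)
        assert model.explained_pct[0] == pytest.approx(50.0, abs=2.0)

    def test_loadings_are_orthonormal(self, rng):
        X = rng.standard_normal((200, 8)) @ rng.standard_normal((8, 8))
        model = pca_fit(X)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_full_reconstruction_recovers_standardized_data(self, rng):
        X = rng.standard_normal((100, 5)) * [1, 10, 100, 1000, 0.1]
        model = pca_fit(X)
        Z = (X - model.mean) / model.scale
        scores = pca_transform(model, X)
        assert np.allclose(scores @ model.components, Z, atol=1e-8)

    def test_non_finite_column_is_named(self):
        X = np.ones((10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="beta"):
            pca_fit(X, feature_names=["alpha", "beta"])


class TestCumulativeVarianceThreshold:
    def test_published_variances_keep_11_at_94pct(self):
        assert select_pcs_by_cumulative_variance(
            PUBLISHED_EXPLAINED_PCT, 94.0) == 11

    def test_published_variances_keep_13_at_98pct(self):
        assert select_pcs_by_cumulative_variance(
            PUBLISHED_EXPLAINED_PCT, 98.0) == 13

    def test_threshold_100_keeps_everything(self):
        assert select_pcs_by_cumulative_variance(
            PUBLISHED_EXPLAINED_PCT, 100.0) == 13

    def test_cumulative_is_monotone(self, rng):
        model = pca_fit(rng.standard_normal((300, 6)))
        assert np.all(np.diff(model.cumulative_pct) >= -1e-12)


class TestPcReranking:
    def test_delegates_to_mrmr_on_scores(self, rng):
        n = 500
        y = rng.integers(0, 2, n)
        X = np.column_stack([y + 0.2 * rng.standard_normal(n),
                             rng.standard_normal(n),
                             rng.standard_normal(n)])
        model = pca_fit(X)
        scores = pca_transform(model, X)
        rk = rank_pcs_mrmr(scores, y)
        direct = mrmr_rank(scores, y,
                           feature_names=[f"PC{i+1}" for i in range(3)])
        assert rk.order == direct.order

    def test_uninformative_pc_ranks_last(self):
        rng = np.random.default_rng(4)
        n = 4000
        y = rng.integers(0, 2, n)
        informative1 = y * 2.0 + 0.1 * rng.standard_normal(n)
        informative2 = -y + 0.1 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        scores = np.column_stack([informative1, noise, informative2])
        rk = rank_pcs_mrmr(scores, y)
        assert rk.order[-1] == "PC2"


class TestPipelineProperty:
    def test_informative_features_rank_before_noise(self):
        """Three stage-coupled features must all precede seven pure-noise
        features in the mRMR ranking."""
        rng = np.random.default_rng(6)
        n = 5000
        y = rng.integers(0, 3, n)
        informative = [
            y + 0.3 * rng.standard_normal(n),
            (y == 0) + 0.3 * rng.standard_normal(n),
            y ** 2 + 0.5 * rng.standard_normal(n),
        ]
        noise = [rng.standard_normal(n) for _ in range(7)]
        names = [f"inf{i}" for i in range(3)] + [f"noise{i}" for i in range(7)]
        rk = mrmr_rank(np.column_stack(informative + noise), y,
                       feature_names=names)
        first_noise = min(rk.order.index(f"noise{i}") for i in range(7))
        last_informative = max(rk.order.index(f"inf{i}") for i in range(3))
        assert last_informative < first_noise
        model = pca_fit(np.column_stack(informative + noise))
        assert model.components.shape == (10, 10)
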