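import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from epidiff.discriminant import (cross_validate, lda_fit, pca_reduce,
                                  pillai_trace, region_feature_matrix,
                                  ward_cluster)


def gaussian_groups(means, sd, n_per_group, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(m, sd, size=(n_per_group, len(m)))
                   for m in means])
    labels = np.repeat([f"g{i}" for i in range(len(means))], n_per_group)
    return X, labels


class TestRegionFeatureMatrix:
    def _matrix(self):
        rows = [("Chr1", p, "+", "CG", [(3, 12), (9, 12)])
                for p in (100, 150, 200)]
        rows += [("Chr1", p, "+", "CG", [(12, 12), (0, 0)])
                 for p in (1000, 1050)]
        return make_matrix(rows, ["s1", "s2"])

    def test_pooled_levels(self):
        regions = pd.DataFrame({"chrom": ["Chr1"], "start": [100],
                                "end": [200]})
        X = region_feature_matrix(regions, self._matrix())
        assert X.loc["s1"].iloc[0] == pytest.approx(0.25)
        assert X.loc["s2"].iloc[0] == pytest.approx(0.75)

    def test_zero_coverage_region_dropped(self):
        regions = pd.DataFrame({"chrom": ["Chr1", "Chr1"],
                                "start": [100, 1000], "end": [200, 1100]})
        X = region_feature_matrix(regions, self._matrix())
        assert X.shape[1] == 1  # second region has cov 0 in s2

    def test_all_regions_dropped_is_an_error(self):
        regions = pd.DataFrame({"chrom": ["Chr1"], "start": [1000],
                                "end": [1100]})
        with pytest.raises(ValueError):
            region_feature_matrix(regions, self._matrix())


class TestPca:
    def test_collinear_points_have_one_component(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        res = pca_reduce(X, n_components=2)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_constant_column_contributes_nothing(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=10), np.full(10, 3.14)])
        res = pca_reduce(X, n_components=1)
        assert res.components[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 50))
        res = pca_reduce(X, n_components=4)
        # independent route: eigendecomposition of the sample covariance
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:4]
        expected = (X - X.mean(0)) @ evecs[:, order]
        for k in range(4):
            dot = np.dot(res.scores[:, k], expected[:, k])
            sign = 1.0 if dot >= 0 else -1.0
            assert np.allclose(res.scores[:, k], sign * expected[:, k],
                               atol=1e-8)

    def test_reconstruction_error_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 12))
        errs = []
        for k in range(1, 8):
            res = pca_reduce(X, n_components=k)
            recon = res.scores @ res.components + res.mean
            errs.append(((X - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_excess_components_clipped_with_warning(self):
        X = np.random.default_rng(1).normal(size=(3, 10))
        with pytest.warns(UserWarning, match="clipped"):
            res = pca_reduce(X, n_components=9)
        assert res.scores.shape[1] == 2


class TestLda:
    def test_axis_aligned_separation(self):
        X, labels = gaussian_groups([(0.0, 0.0), (10.0, 0.0)], sd=0.3,
                                    n_per_group=5, seed=1)
        res = lda_fit(X, labels, n_functions=1)
        w = res.directions[:, 0]
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine > 0.99

    def test_identical_means_give_null_eigenvalues(self):
        X, labels = gaussian_groups([(0.0, 0.0)] * 3, sd=1.0,
                                    n_per_group=5, seed=2)
        res = lda_fit(X, labels, n_functions=2)
        assert (res.eigenvalues < 0.5).all()

    def test_three_group_centroid_assignment(self):
        X, labels = gaussian_groups([(0, 0), (10, 0), (0, 10)], sd=0.1,
                                    n_per_group=3, seed=3)
        res = lda_fit(X, labels, n_functions=2)
        cents = res.group_centroids
        for coord, lab in zip(res.coordinates, labels):
            d = ((cents.to_numpy() - coord) ** 2).sum(axis=1)
            assert cents.index[np.argmin(d)] == lab

    def test_matches_scatter_matrix_oracle(self):
        X, labels = gaussian_groups([(0, 0, 1), (3, 1, 0)], sd=0.5,
                                    n_per_group=4, seed=6)
        res = lda_fit(X, labels, n_functions=1)
        # brute-force: Sw^-1 Sb eigenvector for two groups is along
        # Sw^-1 (m1 - m2)
        m1 = X[labels == "g0"].mean(0)
        m2 = X[labels == "g1"].mean(0)
        Sw = sum(np.cov(X[labels == g], rowvar=False) *
                 (sum(labels == g) - 1) for g in ("g0", "g1"))
        w_oracle = np.linalg.solve(Sw, m1 - m2)
        w = res.directions[:, 0]
        cosine = abs(w @ w_oracle) / (np.linalg.norm(w) *
                                      np.linalg.norm(w_oracle))
        assert cosine > 0.999

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            lda_fit(X, ["g"] * 5)


class TestWard:
    def test_separated_triplets_recovered(self):
        X, labels = gaussian_groups([(0, 0), (50, 0), (0, 50)], sd=0.5,
                                    n_per_group=3, seed=7)
        _, cut = ward_cluster(X, k=3)
        # perfect agreement: each true group is one cluster
        mapping = {}
        for c, l in zip(cut, labels):
            mapping.setdefault(l, set()).add(c)
        assert all(len(v) == 1 for v in mapping.values())
        assert len(set.union(*mapping.values())) == 3

    def test_identical_points_merge_at_zero_height(self):
        X = np.ones((4, 2))
        Z, _ = ward_cluster(X, k=2)
        assert np.allclose(Z[:, 2], 0.0)

    def test_line_split_matches_exhaustive_partition_oracle(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        _, cut = ward_cluster(pts, k=2)
        # oracle: minimise total within-cluster sum of squares over all
        # 2-partitions
        best, best_ss = None, np.inf
        idx = range(6)
        for r in range(1, 6):
            for left in itertools.combinations(idx, r):
                right = [i for i in idx if i not in left]
                ss = sum(((pts[list(g)] - pts[list(g)].mean(0)) ** 2).sum()
                         for g in (left, right))
                if ss < best_ss:
                    best_ss, best = ss, set(left)
        got = {i for i in idx if cut[i] == cut[0]}
        assert got == best or got == set(idx) - best

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((3, 2)), k=4)


class TestPillai:
    def test_identical_group_sets_give_zero(self):
        base = np.random.default_rng(1).normal(size=(4, 2))
        X = np.vstack([base, base])
        labels = ["a"] * 4 + ["b"] * 4
        stat, _ = pillai_trace(X, labels)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_well_separated_three_groups_near_upper_bound(self):
        X, labels = gaussian_groups([(0, 0), (10, 0), (0, 10)], sd=0.01,
                                    n_per_group=3, seed=8)
        stat, p = pillai_trace(X, labels)
        assert 1.99 <= stat <= 2.0
        assert p < 0.01

    def test_never_exceeds_analytic_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = int(rng.integers(2, 5))
            d = int(rng.integers(1, 5))
            n = int(rng.integers(2, 5))
            X = rng.normal(size=(g * n, d))
            labels = np.repeat([f"g{i}" for i in range(g)], n)
            stat, _ = pillai_trace(X, labels)
            assert -1e-10 <= stat <= min(g - 1, d) + 1e-10

    def test_matches_manova_cross_check(self):
        from statsmodels.multivariate.manova import MANOVA
        X, labels = gaussian_groups([(0, 0, 0), (2, 1, 0), (0, 1, 2)],
                                    sd=1.0, n_per_group=6, seed=10)
        stat, p = pillai_trace(X, labels)
        df = pd.DataFrame(X, columns=["y1", "y2", "y3"])
        df["g"] = labels
        res = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
        tbl = res.results["g"]["stat"]
        assert stat == pytest.approx(tbl.loc["Pillai's trace", "Value"],
                                     rel=1e-4)
        assert p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"],
                                  rel=1e-3, abs=1e-10)


class TestCrossValidate:
    def test_perfect_separation_scores_one(self):
        X, labels = gaussian_groups([(0,) * 6, (10,) * 6], sd=0.2,
                                    n_per_group=6, seed=11)
        for clf in ("lda", "svm"):
            res = cross_validate(X, labels, classifier=clf, folds=10,
                                 repeats=5, seed=1)
            assert res.mean_accuracy == 1.0

    def test_fold_count_capped_by_smallest_class(self):
        X, labels = gaussian_groups([(0, 0), (5, 5), (9, 0)], sd=0.5,
                                    n_per_group=3, seed=12)
        res = cross_validate(X, labels, folds=10, repeats=2, seed=0)
        assert res.folds == 3

    def test_same_seed_reproduces_per_repeat_accuracies(self):
        X, labels = gaussian_groups([(0, 0), (3, 3)], sd=1.5,
                                    n_per_group=5, seed=13)
        r1 = cross_validate(X, labels, repeats=2, seed=5)
        r2 = cross_validate(X, labels, repeats=2, seed=5)
        assert np.array_equal(r1.per_repeat, r2.per_repeat)

    def test_unknown_classifier_rejected(self):
        X, labels = gaussian_groups([(0,), (5,)], sd=0.1, n_per_group=3)
        with pytest.raises(ValueError):
            cross_validate(X, labels, classifier="forest", repeats=1)
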