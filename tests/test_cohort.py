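"""Ward clustering, infiltration scoring and PCA machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immunopolar.cohort import (
    infiltration_score,
    pca_fit,
    pca_noise_thresholds,
    project_onto_loadings,
    ward_cluster,
)


def _frame(X, prefix="s"):
    """genes x samples frame from a samples x genes array."""
    X = np.atleast_2d(X)
    return pd.DataFrame(
        X.T,
        index=[f"g{i}" for i in range(X.shape[1])],
        columns=[f"{prefix}{i}" for i in range(X.shape[0])],
    )


class TestWardCluster:
    def test_separated_pairs(self):
        df = _frame(np.array([[0.0], [1.0], [10.0], [11.0]]))
        res = ward_cluster(df, 2)
        assert res.labels["s0"] == res.labels["s1"]
        assert res.labels["s2"] == res.labels["s3"]
        assert res.labels["s0"] != res.labels["s2"]

    def test_singletons_when_k_equals_n(self):
        df = _frame(np.arange(4.0)[:, None] * 3)
        res = ward_cluster(df, 4)
        assert res.labels.nunique() == 4

    def test_too_many_groups_rejected(self):
        df = _frame(np.arange(3.0)[:, None])
        with pytest.raises(ValueError):
            ward_cluster(df, 4)

    def test_largest_cluster_is_group_one(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((2, 2)) * 9])
        res = ward_cluster(_frame(X), 2)
        assert (res.labels == 1).sum() == 5

    def test_two_cut_matches_exhaustive_wss_oracle(self):
        # well-separated blobs: the tree's 2-cut must be the global best
        # 2-partition by total within-cluster sum of squares
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 0.3, (4, 3)), rng.normal(5, 0.3, (4, 3))])
        res = ward_cluster(_frame(X), 2)

        def wss(part):
            tot = 0.0
            for idx in part:
                if idx:
                    sub = X[list(idx)]
                    tot += ((sub - sub.mean(axis=0)) ** 2).sum()
            return tot

        best, best_w = None, np.inf
        for mask in range(1, 2 ** (len(X) - 1)):
            a = [i for i in range(len(X)) if mask >> i & 1]
            b = [i for i in range(len(X)) if not mask >> i & 1]
            w = wss([a, b])
            if w < best_w:
                best, best_w = frozenset(map(frozenset, [a, b])), w
        got = frozenset(
            frozenset(int(s[1:]) for s in res.labels.index[res.labels == g])
            for g in res.labels.unique()
        )
        assert got == best

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        for method in ("ward.D2", "ward.D"):
            res = ward_cluster(_frame(rng.normal(size=(12, 5))), 2, method=method)
            assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(8)
        df = _frame(rng.normal(size=(10, 4)))
        shuffled = df[list(rng.permutation(df.columns))]
        a = ward_cluster(df, 3)
        b = ward_cluster(shuffled, 3)
        pd.testing.assert_series_equal(a.labels.sort_index(), b.labels.sort_index())

    def test_ward_d_variant_agrees_on_clear_structure(self):
        X = np.vstack([np.zeros((4, 2)), np.full((3, 2), 8.0)])
        d2 = ward_cluster(_frame(X), 2, method="ward.D2")
        d1 = ward_cluster(_frame(X), 2, method="ward.D")
        pd.testing.assert_series_equal(d1.labels, d2.labels)


class TestInfiltration:
    def test_mean_over_markers(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["m1", "m2", "m3"]
        )
        assert infiltration_score(df, ["m1", "m2", "m3"])["s1"] == pytest.approx(2.0)

    def test_missing_marker_warns_and_averages_rest(self, caplog):
        df = pd.DataFrame({"s1": [1.0, 3.0]}, index=["m1", "m2"])
        score = infiltration_score(df, ["m1", "m2", "absent"])
        assert score["s1"] == pytest.approx(2.0)
        assert "ABSENT" in caplog.text

    def test_no_marker_present_is_error(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            infiltration_score(df, ["nope"])

    def test_planted_group_offset_recovered(self):
        rng = np.random.default_rng(12)
        lo = rng.normal(0.0, 1.0, (4, 200))
        hi = rng.normal(1.0, 1.0, (4, 200))
        df = pd.DataFrame(
            np.hstack([lo, hi]),
            index=["m1", "m2", "m3", "m4"],
            columns=[f"a{i}" for i in range(200)] + [f"b{i}" for i in range(200)],
        )
        s = infiltration_score(df, ["m1", "m2", "m3", "m4"])
        diff = s[[c for c in s.index if c.startswith("b")]].mean() - s[
            [c for c in s.index if c.startswith("a")]
        ].mean()
        assert diff == pytest.approx(1.0, abs=3 * 0.5 / np.sqrt(200))


class TestPCA:
    def test_closed_form_two_gene_case(self):
        # covariance [[2,1],[1,2]] -> eigenvalues 3, 1; PC1 along (1,1)/sqrt(2)
        rng = np.random.default_rng(9)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = rng.normal(size=(4000, 2)) @ L.T
        res = pca_fit(_frame(X))
        assert res.variance_fraction[0] == pytest.approx(0.75, abs=0.02)
        np.testing.assert_allclose(
            np.abs(res.loadings["PC1"]), 1 / np.sqrt(2), atol=0.02
        )

    def test_loadings_orthonormal_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(10)
        res = pca_fit(_frame(rng.normal(size=(15, 6))))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert (res.variance_fraction >= 0).all()

    def test_reconstruction(self):
        rng = np.random.default_rng(13)
        df = _frame(rng.normal(size=(8, 5)))
        res = pca_fit(df)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.gene_center.to_numpy()
        np.testing.assert_allclose(recon, df.T.to_numpy(), atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(14)
        res = pca_fit(_frame(rng.normal(size=(20, 4))))
        for c in res.loadings.columns:
            v = res.loadings[c].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_degenerate_input_rejected(self):
        df = _frame(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            pca_fit(df)


class TestNoiseThresholdsAndProjection:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(15)
        df = _frame(rng.normal(size=(60, 8)))
        return df, pca_fit(df)

    def test_reproducible_with_seed(self, fitted):
        df, res = fitted
        a = pca_noise_thresholds(df, res, B=100, seed=3)
        b = pca_noise_thresholds(df, res, B=100, seed=3)
        pd.testing.assert_series_equal(a["sd"], b["sd"])

    def test_three_sd_coverage_gaussian_pool(self, fitted):
        df, res = fitted
        out = pca_noise_thresholds(df, res, B=4000, seed=5)
        proj = out["projections"]
        inside = (
            (proj - out["median"]).abs() <= 3 * out["sd"]
        ).all(axis=1)
        # per-component ~99.7%; jointly over 8 comps slightly less
        assert inside.mean() > 0.96

    def test_zero_variance_pool_degenerates(self):
        rng = np.random.default_rng(16)
        df = _frame(rng.normal(size=(10, 4)))
        res = pca_fit(df)
        const = pd.DataFrame(1.0, index=df.index, columns=df.columns)
        out = pca_noise_thresholds(const, res, B=50, seed=0)
        np.testing.assert_allclose(out["sd"], 0.0, atol=1e-12)

    def test_projecting_training_matrix_reproduces_scores(self, fitted):
        df, res = fitted
        proj = project_onto_loadings(df, res)
        np.testing.assert_allclose(proj.to_numpy(), res.scores.to_numpy(), atol=1e-10)

    def test_insufficient_overlap_rejected(self, fitted):
        df, res = fitted
        with pytest.raises(ValueError, match="loading genes"):
            project_onto_loadings(df.iloc[:2], res)

    def test_missing_genes_imputed_at_center(self, fitted, caplog):
        df, res = fitted
        partial = df.iloc[: int(0.75 * len(df.index))]
        proj = project_onto_loadings(partial, res)
        assert proj.shape == res.scores.shape
        assert "imputes" in caplog.text

    def test_external_cohort_from_training_distribution_inside_contour(self, fitted):
        df, res = fitted
        rng = np.random.default_rng(17)
        ext = pd.DataFrame(
            rng.normal(size=df.shape), index=df.index,
            columns=[f"e{i}" for i in range(df.shape[1])],
        )
        proj = project_onto_loadings(ext, res)
        lim = res.scores.abs().max() * 2.5
        assert (proj.abs() <= lim).all(axis=1).mean() >= 0.95
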