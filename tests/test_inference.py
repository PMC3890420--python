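"""Polarization likelihood, posterior, bootstrap null and empirical p-values."""

import numpy as np
import pandas as pd
import pytest

from immunopolar.inference import (
    InferenceConfig,
    bootstrap_null,
    cohort_mean_posterior,
    empirical_pvalue,
    polarization_posterior,
    posterior_frame,
    subset_likelihood,
    subset_log_likelihood,
)
from immunopolar.panels import PanelError

from conftest import naive_posterior, random_disjoint_family


class TestLikelihood:
    def test_symmetry_at_zero_z(self, symmetric_family):
        z = {g: 0.0 for g in symmetric_family.genes}
        ls = [subset_likelihood(z, symmetric_family, k) for k in range(4)]
        assert np.allclose(ls, ls[0])

    def test_maximum_at_target_pattern(self, symmetric_family):
        # z = +a on the subset's own genes and -a elsewhere gives L = 1
        fam = symmetric_family
        z = {g: -1.0 for g in fam.genes}
        for g in fam.exclusive["S2"]:
            z[g] = 1.0
        assert subset_likelihood(z, fam, "S2") == pytest.approx(1.0)
        zoff = dict(z, **{fam.exclusive["S2"][0]: 0.5})
        assert subset_likelihood(zoff, fam, "S2") < 1.0

    def test_two_model_hand_values(self, toy_two_model_family):
        z = {"G1": 1.0, "G2": 0.0}
        assert subset_likelihood(z, toy_two_model_family, 0) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )
        assert subset_likelihood(z, toy_two_model_family, 1) == pytest.approx(
            np.exp(-2.5), rel=1e-12
        )

    def test_missing_gene_named_in_error(self, toy_two_model_family):
        with pytest.raises(PanelError, match="G2"):
            subset_log_likelihood({"G1": 0.0}, toy_two_model_family, 0)


class TestPosterior:
    def test_uniform_at_zero_z(self, symmetric_family):
        z = {g: 0.0 for g in symmetric_family.genes}
        post = polarization_posterior(z, symmetric_family)
        np.testing.assert_allclose(post, 0.25)

    def test_two_model_hand_posterior(self, toy_two_model_family):
        post = polarization_posterior({"G1": 1.0, "G2": 0.0}, toy_two_model_family)
        assert post["A"] == pytest.approx(1 / (1 + np.exp(-2)), rel=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            fam = random_disjoint_family(rng)
            a = float(rng.uniform(0.5, 2.0))
            z = {g: float(rng.normal(0, 2)) for g in fam.genes}
            got = polarization_posterior(z, fam, InferenceConfig(amplitude=a))
            want = naive_posterior(z, fam, amplitude=a)
            np.testing.assert_allclose(got.to_numpy(), want, atol=1e-12)

    def test_label_permutation_equivariance(self, symmetric_family):
        rng = np.random.default_rng(7)
        fam = symmetric_family
        z = {g: float(rng.normal()) for g in fam.genes}
        post = polarization_posterior(z, fam)
        # swap the z-patterns of S0 and S3: posteriors must swap too
        swapped = dict(z)
        for a, b in zip(fam.exclusive["S0"], fam.exclusive["S3"]):
            swapped[a], swapped[b] = z[b], z[a]
        post2 = polarization_posterior(swapped, fam)
        assert post2["S0"] == pytest.approx(post["S3"], rel=1e-10)
        assert post2["S3"] == pytest.approx(post["S0"], rel=1e-10)

    def test_extreme_z_does_not_underflow(self, symmetric_family):
        z = {g: 80.0 for g in symmetric_family.exclusive["S0"]}
        z.update({g: -80.0 for g in symmetric_family.genes if g not in z})
        post = polarization_posterior(z, symmetric_family)
        assert np.isfinite(post).all()
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert post.idxmax() == "S0"

    def test_monotone_in_own_gene(self, toy_two_model_family):
        grid = np.linspace(-3, 3, 13)
        ps = [
            polarization_posterior({"G1": g, "G2": 0.0}, toy_two_model_family)["A"]
            for g in grid
        ]
        assert np.all(np.diff(ps) > 0)

    def test_nonuniform_prior_shifts_posterior(self, toy_two_model_family):
        z = {"G1": 0.0, "G2": 0.0}
        cfg = InferenceConfig(prior=(0.9, 0.1))
        post = polarization_posterior(z, toy_two_model_family, cfg)
        assert post["A"] == pytest.approx(0.9, rel=1e-12)


class TestCohortMeans:
    def test_single_sample_cohort_is_its_posterior(self, symmetric_family):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(
            rng.normal(size=(len(symmetric_family.genes), 3)),
            index=list(symmetric_family.genes), columns=["a", "b", "c"],
        )
        post = posterior_frame(z, symmetric_family)
        means = cohort_mean_posterior(
            z, symmetric_family, membership={"a": "x", "b": "y", "c": "y"}
        )
        np.testing.assert_allclose(means.loc["x"], post.loc["a"])
        np.testing.assert_allclose(
            means.loc["y"], (post.loc["b"] + post.loc["c"]) / 2
        )

    def test_means_on_simplex(self, symmetric_family):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(
            rng.normal(size=(len(symmetric_family.genes), 20)),
            index=list(symmetric_family.genes),
            columns=[f"s{i}" for i in range(20)],
        )
        means = cohort_mean_posterior(z, symmetric_family)
        assert means.to_numpy().min() >= 0
        np.testing.assert_allclose(means.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_sample_membership_error(self, symmetric_family):
        z = pd.DataFrame(
            np.zeros((len(symmetric_family.genes), 2)),
            index=list(symmetric_family.genes), columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="membership"):
            cohort_mean_posterior(z, symmetric_family, membership={"a": "x"})


class TestBootstrapNull:
    @pytest.fixture
    def zpool(self):
        rng = np.random.default_rng(3)
        return pd.DataFrame(
            rng.normal(size=(30, 40)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(40)],
        )

    def test_single_replicate_on_simplex(self, zpool, symmetric_family):
        null = bootstrap_null(zpool, symmetric_family, B=1, n_cohort=5, seed=0)
        assert null.b == 1
        np.testing.assert_allclose(null.replicates.sum(axis=1), 1.0, atol=1e-12)

    def test_seed_reproducibility(self, zpool, symmetric_family):
        a = bootstrap_null(zpool, symmetric_family, B=20, n_cohort=10, seed=9)
        b = bootstrap_null(zpool, symmetric_family, B=20, n_cohort=10, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_empirical_pvalue_add_one_rule(self, zpool, symmetric_family):
        null = bootstrap_null(zpool, symmetric_family, B=99, n_cohort=5, seed=2)
        assert empirical_pvalue(2.0, null, "S0") == pytest.approx(1 / 100)
        med = float(null.replicates["S0"].median())
        assert empirical_pvalue(med, null, "S0") == pytest.approx(0.5, abs=0.02)

    def test_kde_present_per_subset(self, zpool, symmetric_family):
        null = bootstrap_null(zpool, symmetric_family, B=50, n_cohort=10, seed=4)
        assert set(null.kde) == set(symmetric_family.subset_names)
        dens = null.kde["S1"](0.25)
        assert np.isfinite(dens).all() and dens[0] > 0
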