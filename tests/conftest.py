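import math

import numpy as np
import pandas as pd
import pytest

from immunopolar.panels import GeneSignature, SignatureFamily, reduce_to_exclusive


@pytest.fixture
def toy_two_model_family():
    """K=2, one exclusive gene per subset."""
    fam = SignatureFamily(
        "toy", (GeneSignature("A", ("G1",)), GeneSignature("B", ("G2",)))
    )
    return reduce_to_exclusive(fam)


@pytest.fixture
def symmetric_family():
    """Four disjoint subsets of three genes each (exchangeable under the null)."""
    subs = tuple(
        GeneSignature(f"S{k}", tuple(f"G{k}_{i}" for i in range(3))) for k in range(4)
    )
    return reduce_to_exclusive(SignatureFamily("sym", subs))


def naive_posterior(z, family, amplitude=1.0, priors=None):
    """Direct per-gene product evaluation of the polarization posterior.

    Multiplies per-gene Gaussian kernels in linear space, exactly as the
    model is written down; deliberately independent of the package's
    vectorized log-space implementation.
    """
    names = family.subset_names
    K = len(names)
    likes = []
    for k in range(K):
        L = 1.0
        for j, other in enumerate(names):
            target = amplitude if j == k else -amplitude
            for g in family.exclusive[other]:
                L *= math.exp(-0.5 * (z[g] - target) ** 2)
        prior = priors[k] if priors is not None else 1.0 / K
        likes.append(L * prior)
    tot = sum(likes)
    return [l / tot for l in likes]


def random_disjoint_family(rng, k=None, max_size=4):
    """A random family of disjoint subsets for oracle comparisons."""
    k = k or int(rng.integers(2, 5))
    sizes = rng.integers(1, max_size + 1, size=k)
    genes = iter(f"G{i}" for i in range(int(sizes.sum())))
    subs = tuple(
        GeneSignature(f"S{j}", tuple(next(genes) for _ in range(sizes[j])))
        for j in range(k)
    )
    return reduce_to_exclusive(SignatureFamily("rand", subs))


@pytest.fixture
def raw_matrix():
    """Small strictly positive raw-intensity matrix."""
    rng = np.random.default_rng(11)
    vals = rng.lognormal(mean=3.0, sigma=0.8, size=(6, 5))
    return pd.DataFrame(
        vals,
        index=[f"GENE{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(5)],
    )
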