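"""Cohort structure: Ward clustering, infiltration scores, PCA with noise
thresholds and cross-study projection.

Samples are clustered on the immune gene panel with Ward's minimum-variance
criterion; the two-group cut of the tree defines the patient cohorts (the
larger cluster is labeled group 1).  The magnitude of immune infiltration is
the per-sample mean of log2 median-centered values over NK / T cell /
macrophage recruitment markers.  PCA of the per-gene-centered panel matrix
summarizes covariation; bootstrap resampling of the pooled expression values
gives per-component noise thresholds, and external cohorts are compared by
projecting them onto the fitted loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix
from .panels import canonical_symbol

logger = logging.getLogger("immunopolar")

__all__ = [
    "CohortAssignment",
    "PCAResult",
    "ward_cluster",
    "infiltration_score",
    "pca_fit",
    "pca_noise_thresholds",
    "project_onto_loadings",
]

#: sd multiples at which bootstrap noise ellipses are reported
NOISE_SD_MULTIPLES = (1, 2, 3, 5, 7)


@dataclass
class CohortAssignment:
    """Sample -> group labels plus the linkage tree behind the cut."""

    labels: pd.Series  # sample id -> group number (1-based, 1 = largest)
    linkage: np.ndarray  # scipy linkage matrix over the sorted sample order
    sample_order: tuple[str, ...]
    method: str

    @property
    def n_groups(self) -> int:
        return int(self.labels.nunique())

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class PCAResult:
    """Orthonormal gene loadings, sample scores and variance fractions."""

    loadings: pd.DataFrame  # genes x components
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    gene_center: pd.Series
    gene_scale: pd.Series | None = None  # set when fitted on correlations


def _values(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, ExpressionMatrix) else m


def _restrict(df: pd.DataFrame, genes: Iterable[str] | None) -> pd.DataFrame:
    if genes is None:
        return df
    wanted = [canonical_symbol(g) for g in genes]
    by_canon = {canonical_symbol(i): i for i in df.index}
    present = [by_canon[g] for g in wanted if g in by_canon]
    missing = sorted(g for g in wanted if g not in by_canon)
    if missing:
        logger.warning("genes absent from matrix: %s", ", ".join(missing))
    if not present:
        raise ValueError("none of the requested genes are in the matrix")
    return df.loc[present]


def _ward_d_linkage(d: np.ndarray) -> np.ndarray:
    """Lance-Williams agglomeration with Ward coefficients on the given
    dissimilarities (R's ``ward.D``: the input distances are treated as if
    squared).  Naive O(n^3); used only for the non-default variant.
    Ties are broken by the lowest (i, j) index pair."""
    n = d.shape[0]
    D = d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    node_id = {i: i for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if D[i, j] < best[0]:
                    best = (D[i, j], i, j)
        h, i, j = best
        ni, nj = sizes[i], sizes[j]
        Z[step] = [node_id[i], node_id[j], max(h, 0.0), ni + nj]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            D[i, k] = D[k, i] = (
                (ni + nk) * D[i, k] + (nj + nk) * D[j, k] - nk * h
            ) / (ni + nj + nk)
        sizes[i] = ni + nj
        node_id[i] = n + step
        active.remove(j)
    # heights are the Lance-Williams criterion values (R ward.D convention);
    # Ward merges are monotone, enforce against round-off for fcluster
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])
    return Z


def ward_cluster(
    m: ExpressionMatrix | pd.DataFrame,
    n_groups: int,
    genes: Iterable[str] | None = None,
    method: str = "ward.D2",
) -> CohortAssignment:
    """Ward hierarchical clustering of samples, cut into ``n_groups`` groups.

    Samples are ordered lexicographically before linkage so the result is
    invariant to input order.  Groups are renumbered by decreasing size
    (largest = group 1; ties broken by smallest member sample id).
    ``method`` is ``"ward.D2"`` (the textbook Ward objective on Euclidean
    distances, scipy's ward) or ``"ward.D"`` (R's variant on unsquared
    distances).
    """
    df = _restrict(_values(m), genes)
    order = sorted(df.columns)
    X = df[order].T.to_numpy(dtype=float)  # samples x genes
    if n_groups > len(order):
        raise ValueError(f"n_groups={n_groups} exceeds {len(order)} samples")
    if method == "ward.D2":
        Z = linkage(X, method="ward")
    elif method == "ward.D":
        Z = _ward_d_linkage(squareform(pdist(X)))
    else:
        raise ValueError(f"unknown Ward variant {method!r}")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    labels = pd.Series(raw, index=order)
    # renumber: largest cluster first, ties by smallest member id
    keyed = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), min(kv[1])),
    )
    remap = {old: new + 1 for new, (old, _) in enumerate(keyed)}
    labels = labels.map(remap)
    return CohortAssignment(
        labels=labels, linkage=Z, sample_order=tuple(order), method=method
    )


def infiltration_score(
    m: ExpressionMatrix | pd.DataFrame, markers: Iterable[str]
) -> pd.Series:
    """Per-sample mean log2 median-centered expression over marker genes.

    Markers missing from the matrix are dropped with a warning; having no
    marker present is an error.
    """
    df = _restrict(_values(m), markers)
    return df.mean(axis=0)


def pca_fit(
    m: ExpressionMatrix | pd.DataFrame,
    genes: Iterable[str] | None = None,
    use_correlation: bool = False,
) -> PCAResult:
    """PCA of the gene-gene covariance of per-gene-centered values.

    Components are ordered by decreasing explained variance; each loading's
    sign is fixed so its largest-magnitude entry is positive.  With
    ``use_correlation`` genes are also scaled to unit variance before the
    eigendecomposition.
    """
    df = _restrict(_values(m), genes)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    X = df.T.to_numpy(dtype=float)  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    scale = None
    if use_correlation:
        scale = Xc.std(axis=0, ddof=1)
        if (scale == 0).any():
            raise ValueError("zero-variance gene; correlation PCA undefined")
        Xc = Xc / scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    var = s**2 / (n - 1)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    if not keep.any():
        raise ValueError("degenerate (rank 0) input")
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    # sign convention: largest-|loading| entry positive per component
    for c in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, i] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=df.index, columns=comp),
        scores=pd.DataFrame(U * s, index=df.columns, columns=comp),
        variance_fraction=var / var.sum(),
        gene_center=pd.Series(center, index=df.index),
        gene_scale=None if scale is None else pd.Series(scale, index=df.index),
    )


def pca_noise_thresholds(
    m: ExpressionMatrix | pd.DataFrame,
    pca: PCAResult,
    B: int = 1000,
    seed: int | None = None,
    genes: Iterable[str] | None = None,
) -> dict[str, object]:
    """Noise ellipses from bootstrap-resampled synthetic samples.

    B synthetic samples are drawn value-wise (with replacement) from the pool
    of all expression values, projected onto the fitted loadings, and each
    component's projection summarized by its median and sd.  Ellipse radii at
    the conventional sd multiples (1, 2, 3, 5, 7) quantify how far real
    samples stand out from structureless noise.
    """
    df = _values(m).loc[pca.loadings.index]
    pool = df.to_numpy(dtype=float).ravel()
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(B, len(pca.loadings.index)), replace=True)
    Xc = draws - pca.gene_center.to_numpy()
    if pca.gene_scale is not None:
        Xc = Xc / pca.gene_scale.to_numpy()
    proj = Xc @ pca.loadings.to_numpy()
    med = np.median(proj, axis=0)
    sd = proj.std(axis=0, ddof=1)
    return {
        "median": pd.Series(med, index=pca.loadings.columns),
        "sd": pd.Series(sd, index=pca.loadings.columns),
        "ellipses": {
            mult: pd.Series(mult * sd, index=pca.loadings.columns)
            for mult in NOISE_SD_MULTIPLES
        },
        "projections": pd.DataFrame(proj, columns=pca.loadings.columns),
        "seed": seed,
    }


def project_onto_loadings(
    m: ExpressionMatrix | pd.DataFrame, pca: PCAResult
) -> pd.DataFrame:
    """Project an external cohort onto fitted loadings (cross-study check).

    The external matrix must share at least half of the loading genes; genes
    it lacks contribute 0 after centering (they are imputed at the training
    mean, with a warning).
    """
    df = _values(m)
    genes = list(pca.loadings.index)
    present = [g for g in genes if g in df.index]
    if len(present) < 0.5 * len(genes):
        raise ValueError(
            f"external matrix shares only {len(present)}/{len(genes)} loading genes"
        )
    missing = [g for g in genes if g not in df.index]
    if missing:
        logger.warning(
            "projection imputes %d missing genes at the training mean: %s",
            len(missing), ", ".join(missing),
        )
    X = pd.DataFrame(
        np.tile(pca.gene_center.to_numpy()[:, None], (1, df.shape[1])),
        index=genes, columns=df.columns,
    )
    X.loc[present] = df.loc[present].to_numpy()
    Xc = X.T.to_numpy(dtype=float) - pca.gene_center.to_numpy()
    if pca.gene_scale is not None:
        Xc = Xc / pca.gene_scale.to_numpy()
    return pd.DataFrame(
        Xc @ pca.loadings.to_numpy(), index=df.columns, columns=pca.loadings.columns
    )
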