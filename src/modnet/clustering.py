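"""Co-expression modules: k-means over condition profiles with BIC-selected K.

Genes are clustered on replicate-averaged log2(FPKM + 1) profiles that are
z-scored per gene, so modules capture profile *shape* rather than absolute
expression level.  The number of clusters is chosen by scanning a K grid
and taking the minimum of the spherical-Gaussian mixture BIC (the X-means
formulation): hard-assignment log-likelihood

    ln L = sum_i n_i ln(n_i / n) - (n d / 2) ln(2 pi sigma^2)
           - d (n - K) / 2,

with pooled within-cluster variance sigma^2 = WSS / (d (n - K)), n genes,
d conditions, cluster sizes n_i, and

    BIC(K) = -2 ln L + p ln(n),    p = (K - 1) + K d + 1

free parameters (mixing proportions, centroids, shared variance).  The
cluster-proportion term matters in practice: a likelihood-only spherical
BIC under-penalizes splitting genuine modules at the few-hundred-gene,
few-dozen-condition scale this pipeline runs at.  Lower is better; ties
go to the smaller K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression_io import ExpressionMatrix


@dataclass
class ClusteringConfig:
    k_grid: tuple[int, ...] = tuple(range(20, 101, 5))
    n_restarts: int = 25
    max_iter: int = 300
    seed: int = 0
    input_transform: str = "log2_fpkm_plus1_zscore"

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_grid)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_grid must be strictly increasing")
        if ks and ks[0] < 1:
            raise ValueError("k must be >= 1")
        self.k_grid = ks


@dataclass
class ModuleSet:
    """A partition of genes into K modules with per-module mean profiles."""

    assignment: pd.Series  # gene_id -> module id in 1..K
    K: int
    centroids: np.ndarray
    bic_by_k: dict[int, float]
    module_means: pd.DataFrame  # module id x condition

    def __post_init__(self) -> None:
        mods = set(self.assignment.unique())
        if mods - set(range(1, self.K + 1)):
            raise ValueError("module IDs must lie in 1..K")

    @property
    def module_ids(self) -> list[int]:
        return list(self.module_means.index)

    def members(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])

    def validate_against(self, X: pd.DataFrame, atol: float = 1e-8) -> None:
        """Check stored module means equal recomputed member means."""
        recomputed = module_mean_profiles(self, X)
        if not np.allclose(recomputed.to_numpy(), self.module_means.to_numpy(), atol=atol):
            raise ValueError("module_means inconsistent with assignment")


def transform_profiles(m: ExpressionMatrix, transform: str = "log2_fpkm_plus1_zscore") -> pd.DataFrame:
    """Prepare clustering input from a replicate-averaged FPKM matrix."""
    X = m.data.to_numpy(dtype=float)
    if transform in ("log2_fpkm_plus1", "log2_fpkm_plus1_zscore"):
        X = np.log2(X + 1.0)
    if transform in ("zscore_rows", "log2_fpkm_plus1_zscore"):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # constant rows map to all-zero profiles
        X = (X - mu) / sd
    elif transform == "none":
        pass
    elif transform not in ("log2_fpkm_plus1",):
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(X, index=m.data.index, columns=m.data.columns)


def kmeans_fit(
    X: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd k-means (k-means++ seeding).

    Returns (labels in 1..k, centroids, total within-cluster SS).
    """
    vals = np.asarray(X, dtype=float)
    if k > vals.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {vals.shape[0]}")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in clustering input")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
    ).fit(vals)
    return km.labels_ + 1, km.cluster_centers_, float(km.inertia_)


def kmeans_bic(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
) -> float:
    """Spherical-Gaussian mixture BIC of a k-means solution (lower is better).

    X-means-style: hard-assignment log-likelihood with mixing proportions
    and a pooled spherical variance, penalized by p ln(n) with
    p = (k - 1) + k d + 1 free parameters.
    """
    vals = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, d = vals.shape
    k = centroids.shape[0]
    diffs = vals - centroids[labels - 1]
    wss = float((diffs**2).sum())
    if n <= k:
        raise ValueError("need more points than clusters for a variance estimate")
    sigma2 = wss / (d * (n - k))
    if sigma2 <= 0:
        warnings.warn("degenerate perfect fit (within-SS = 0); BIC is -inf")
        return float("-inf")
    sizes = np.bincount(labels - 1, minlength=k).astype(float)
    sizes = sizes[sizes > 0]
    loglik = (
        float((sizes * np.log(sizes / n)).sum())
        - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    p = (k - 1) + k * d + 1
    return -2.0 * loglik + p * np.log(n)


def select_k(X: pd.DataFrame, cfg: ClusteringConfig) -> ModuleSet:
    """Fit every K on the grid and return the minimum-BIC ModuleSet."""
    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    bic_by_k: dict[int, float] = {}
    for k in cfg.k_grid:
        labels, centroids, _ = kmeans_fit(
            X, k, seed=cfg.seed, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter
        )
        bic = kmeans_bic(X, labels, centroids)
        bic_by_k[k] = bic
        if best is None or bic < best[0]:  # strict <: ties keep the smaller k
            best = (bic, k, labels, centroids)
    assert best is not None
    _, k, labels, centroids = best
    assignment = pd.Series(labels, index=X.index, name="module_id")
    ms = ModuleSet(
        assignment=assignment,
        K=k,
        centroids=centroids,
        bic_by_k=bic_by_k,
        module_means=pd.DataFrame(index=pd.Index([], name="module_id")),
    )
    ms.module_means = module_mean_profiles(ms, X)
    return ms


def fit_fixed_k(X: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 25) -> ModuleSet:
    """Cluster at a user-fixed K (no BIC scan)."""
    labels, centroids, _ = kmeans_fit(X, k, seed=seed, n_restarts=n_restarts)
    assignment = pd.Series(labels, index=X.index, name="module_id")
    ms = ModuleSet(
        assignment=assignment,
        K=k,
        centroids=centroids,
        bic_by_k={k: kmeans_bic(X, labels, centroids)},
        module_means=pd.DataFrame(index=pd.Index([], name="module_id")),
    )
    ms.module_means = module_mean_profiles(ms, X)
    return ms


def module_mean_profiles(ms: ModuleSet, X: pd.DataFrame) -> pd.DataFrame:
    """Mean condition profile of each module's member genes."""
    missing = [g for g in ms.assignment.index if g not in X.index]
    if missing:
        raise ValueError(f"assignment covers genes absent from X: {missing[:5]}")
    sub = X.loc[ms.assignment.index]
    means = sub.groupby(ms.assignment).mean()
    means.index.name = "module_id"
    return means
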