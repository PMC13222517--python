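"""Expression filtering, log transform and k-means++ gene-dimension reduction.

The autoencoder operates along the gene-expression feature dimension, so
before fitting, genes (not samples) are clustered as points in sample space
and each cluster is collapsed to its mean log2 profile.  This reduces the
input dimension (e.g. 10 000 genes -> 1500 features) to curb overfitting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix

__all__ = [
    "log2_transform",
    "filter_genes_expression",
    "select_high_variance",
    "reduce_by_gene_clustering",
    "apply_gene_clustering",
    "write_cluster_assignment",
    "read_cluster_assignment",
]


def log2_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """log2(value + 1); accepts counts or TPM."""
    if x.space not in ("counts", "tpm"):
        raise ValueError(f"log2_transform expects counts or tpm input, got space={x.space!r}")
    if (x.values < 0).any():
        raise ValueError("negative expression value; cannot log-transform")
    return ExpressionMatrix(
        np.log2(x.values + 1.0), list(x.sample_ids), list(x.feature_ids), "log2"
    )


def filter_genes_expression(
    tpm: ExpressionMatrix,
    counts: ExpressionMatrix,
    tpm_min: float = 0.1,
    count_min: float = 6,
    frac: float = 0.2,
) -> list[str]:
    """Dual-threshold expression filter.

    A gene is kept iff the fraction of samples with TPM > tpm_min AND raw
    count > count_min is at least ``frac`` (strict on the thresholds,
    non-strict on the fraction).
    """
    if tpm.values.shape != counts.values.shape or tpm.feature_ids != counts.feature_ids:
        raise ValueError("tpm and counts matrices must share shape and feature ids")
    ok = (tpm.values > tpm_min) & (counts.values > count_min)
    keep = ok.mean(axis=0) >= frac
    return [f for f, k in zip(tpm.feature_ids, keep) if k]


def select_high_variance(x: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the n_top features with largest unbiased sample variance.

    Ties break in favor of earlier columns; the retained features keep their
    original order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > x.n_features:
        raise ValueError(f"n_top={n_top} exceeds n_features={x.n_features}")
    var = x.values.var(axis=0, ddof=1)
    chosen = np.sort(np.argsort(-var, kind="stable")[:n_top])
    return ExpressionMatrix(
        x.values[:, chosen],
        list(x.sample_ids),
        [x.feature_ids[j] for j in chosen],
        x.space,
    )


def reduce_by_gene_clustering(
    x: ExpressionMatrix,
    n_centroids: int,
    seed: int,
    standardize: bool = True,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """k-means++ clustering of genes in sample space; reduced feature j is
    the unweighted mean of the raw log2 values of the genes in cluster j.

    Genes are z-scored across samples before clustering (so high-mean genes
    do not dominate the geometry; disable with ``standardize=False``), but
    raw values are averaged.  Deterministic given ``seed``.
    """
    if x.space != "log2":
        raise ValueError(f"reduction expects log2-space input, got {x.space!r}")
    if n_centroids <= 0:
        raise ValueError("n_centroids must be positive")
    if n_centroids > x.n_features:
        raise ValueError(
            f"n_centroids={n_centroids} exceeds n_features={x.n_features}"
        )
    points = x.values.T  # genes as points in sample space
    if standardize:
        mu = points.mean(axis=1, keepdims=True)
        sd = points.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        points = (points - mu) / sd
    km = KMeans(
        n_clusters=n_centroids,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed % (2**32),
    )
    labels = km.fit_predict(points)
    assignment = {f: int(c) for f, c in zip(x.feature_ids, labels)}
    reduced = _cluster_means(x.values, labels, n_centroids)
    return (
        ExpressionMatrix(
            reduced,
            list(x.sample_ids),
            [f"K{j}" for j in range(n_centroids)],
            "reduced",
        ),
        assignment,
    )


def _cluster_means(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    if (sizes == 0).any():
        raise RuntimeError("empty cluster in reduction")  # KMeans relocates; unreachable
    sums = np.zeros((values.shape[0], k))
    np.add.at(sums.T, labels, values.T)
    return sums / sizes


def apply_gene_clustering(
    x: ExpressionMatrix, assignment: dict[str, int]
) -> ExpressionMatrix:
    """Apply a stored training-time reduction to new data with the same genes."""
    missing = [f for f in assignment if f not in set(x.feature_ids)]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:10]}")
    feats = [f for f in x.feature_ids if f in assignment]
    sub = x.subset_features(feats)
    labels = np.array([assignment[f] for f in feats])
    k = max(assignment.values()) + 1
    reduced = _cluster_means(sub.values, labels, k)
    return ExpressionMatrix(
        reduced, list(x.sample_ids), [f"K{j}" for j in range(k)], "reduced"
    )


def write_cluster_assignment(assignment: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(assignment), "cluster": list(assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_cluster_assignment(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "cluster": int})
    return dict(zip(df["feature_id"], df["cluster"]))
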