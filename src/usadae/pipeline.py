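"""End-to-end fitting: preprocessing (log2 + k-means++ reduction) followed by
three-stage adversarial training, with transform/correct helpers that reuse
the training-time reduction on new data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .model_core import LatentPair, USADAEConfig, USADAEModel, correct_expression, encode, init_model
from .preprocess import apply_gene_clustering, log2_transform, reduce_by_gene_clustering
from .training import TrainingHistory, train

__all__ = ["FittedPipeline", "fit_usadae", "latents_to_frames"]


@dataclass
class FittedPipeline:
    model: USADAEModel
    history: TrainingHistory
    assignment: dict | None  # feature -> cluster, None if input was pre-reduced
    reduced: ExpressionMatrix
    latents: LatentPair

    def transform(self, x: ExpressionMatrix) -> LatentPair:
        return encode(self.model, self._reduce(x))

    def correct(self, x: ExpressionMatrix) -> ExpressionMatrix:
        return correct_expression(self.model, self._reduce(x))

    def _reduce(self, x: ExpressionMatrix) -> ExpressionMatrix:
        if x.space in ("counts", "tpm"):
            x = log2_transform(x)
        if self.assignment is not None and x.space == "log2":
            x = apply_gene_clustering(x, self.assignment)
        return x


def fit_usadae(
    expr: ExpressionMatrix,
    labels,
    config: USADAEConfig | None = None,
    **overrides,
) -> FittedPipeline:
    """Preprocess and train on an expression matrix with per-sample labels.

    Counts/TPM are log2(x+1)-transformed; log2 input is reduced to
    ``config.n_centroids`` cluster-mean features by k-means++ on genes;
    pre-reduced input is used as-is.  Everything derives from
    ``config.seed``.
    """
    if config is None:
        config = USADAEConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    if expr.space in ("counts", "tpm"):
        expr = log2_transform(expr)
    assignment = None
    if expr.space == "log2":
        k = min(config.n_centroids, expr.n_features)
        expr_reduced, assignment = reduce_by_gene_clustering(expr, k, seed=config.seed)
    else:
        expr_reduced = expr
    y = np.asarray(labels)
    if y.dtype.kind not in "iu":
        _, y = np.unique(y, return_inverse=True)
    n_labels = int(y.max()) + 1
    model = init_model(config, D=expr_reduced.n_features, n_labels=max(n_labels, 2))
    model.input_space = expr_reduced.space
    model.feature_clusters = assignment
    model, history = train(model, expr_reduced, y, config)
    latents = encode(model, expr_reduced)
    return FittedPipeline(model, history, assignment, expr_reduced, latents)


def latents_to_frames(pair: LatentPair) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(Zb, Zc) as DataFrames; confounder columns named Conf1..ConfL_c so the
    extracted covariates read naturally in downstream covariate files."""
    zb = pd.DataFrame(
        pair.Zb,
        index=pair.sample_ids,
        columns=[f"Bio{i+1}" for i in range(pair.Zb.shape[1])],
    )
    zc = pd.DataFrame(
        pair.Zc,
        index=pair.sample_ids,
        columns=[f"Conf{i+1}" for i in range(pair.Zc.shape[1])],
    )
    return zb, zc
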