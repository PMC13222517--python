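"""The adversarial deconfounding autoencoder: dual encoders, joint decoder,
independence discriminator and label discriminator.

The model assumes an observed expression profile x (D features per sample)
is generated by a mix of biological signal and hidden covariates.  Two
encoders map x into a biological latent z_b (L dims) and a confounder
latent z_c (L_c dims); a decoder reconstructs x from [z_b; z_c].  A
discriminator D_a tells true pairings [z_b; z_c] from pairings with
row-shuffled z_c — fooling it drives the joint latent distribution toward
the product of its marginals (statistical independence).  A deliberately
small discriminator D_b predicts the condition/tissue label from z_b so the
biological encoder keeps label-discriminative signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import nn
from .data_io import ExpressionMatrix

__all__ = [
    "USADAEConfig",
    "USADAEModel",
    "LatentPair",
    "init_model",
    "encode",
    "decode",
    "discriminate_joint",
    "classify_labels",
    "correct_expression",
]


@dataclass
class USADAEConfig:
    """Hyperparameters of the model and its three-stage training schedule.

    Defaults follow the recommended operating point: latent dims 12,
    bottleneck dropout 0.4 on z_b (0.2 on z_c — see docs/methods.md for the
    reliability asymmetry), label (tissue) weight defaulting to
    lambda_adv + 0.5, Adam at 1e-3 for the autoencoder and the
    independence critic, 1e-4 for the label head, stages of 100/100/500
    epochs.
    """

    L: int = 12
    L_c: int = 12
    dropout: float = 0.4
    conf_dropout: float = 0.2  # lighter dropout on z_c: the decoder's reliable channel
    lambda_adv: float = 0.5
    lambda_tissue: float | None = None  # defaults to lambda_adv + 0.5
    lr_ae: float = 1e-3
    lr_adv: float = 1e-3
    lr_tissue: float = 1e-4
    epochs: tuple[int, int, int] = (100, 100, 500)
    batch_size: int = 128
    seed: int = 0
    linear_decoder: bool = False
    adv_steps: int = 20  # discriminator updates per encoder update, stages 2-3
    critic_mode: Literal["batch", "epoch"] = "batch"
    # fool-gradient damping on the confounder encoder: E_c is the slower
    # adversarial player, so independence is reached by the biological
    # encoder shedding confounder signal rather than z_c emptying out
    conf_fool_scale: float = 0.2
    bio_fool_scale: float = 0.2  # analogous damping for the biological encoder
    n_centroids: int = 750
    db_width: int = 32
    correction: Literal["mean", "zero"] = "mean"

    def __post_init__(self) -> None:
        if self.L < 1 or self.L_c < 1:
            raise ValueError("latent dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lambda_adv <= 0:
            raise ValueError("lambda_adv must be positive")
        if self.lambda_tissue is None:
            self.lambda_tissue = self.lambda_adv + 0.5
        self.epochs = tuple(int(e) for e in self.epochs)
        if len(self.epochs) != 3 or any(e < 0 for e in self.epochs):
            raise ValueError("epochs must be three non-negative stage lengths")
        if not 12 <= self.L <= 32:
            warnings.warn(f"L={self.L} outside the recommended range [12, 32]")
        if not 0.2 <= self.dropout <= 0.6:
            warnings.warn(f"dropout={self.dropout} outside the recommended range [0.2, 0.6]")
        if not 0.5 <= self.lambda_adv <= 2.0:
            warnings.warn(f"lambda_adv={self.lambda_adv} outside the recommended range [0.5, 2]")
        if not 500 <= self.n_centroids <= 2500:
            warnings.warn(
                f"n_centroids={self.n_centroids} outside the recommended range [500, 2500]"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epochs"] = list(self.epochs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "USADAEConfig":
        d = dict(d)
        if "epochs" in d:
            d["epochs"] = tuple(d["epochs"])
        return cls(**d)


@dataclass
class LatentPair:
    """Per-sample biological (Zb) and confounder (Zc) embeddings."""

    Zb: np.ndarray  # n x L
    Zc: np.ndarray  # n x L_c
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Zb = np.asarray(self.Zb, dtype=np.float64)
        self.Zc = np.asarray(self.Zc, dtype=np.float64)
        if self.Zb.shape[0] != self.Zc.shape[0]:
            raise ValueError("Zb and Zc row counts differ")
        if self.sample_ids and len(self.sample_ids) != self.Zb.shape[0]:
            raise ValueError("sample_ids length does not match latent rows")

    @property
    def n(self) -> int:
        return self.Zb.shape[0]


class USADAEModel:
    """Container for the five parameterized networks plus training metadata."""

    def __init__(self, config: USADAEConfig, D: int, n_labels: int, seed: int):
        if n_labels < 2:
            raise ValueError("n_labels must be >= 2 (label discriminator undefined otherwise)")
        if D < config.L + config.L_c:
            raise ValueError(
                f"input dimension D={D} smaller than total latent dimension "
                f"{config.L + config.L_c}"
            )
        self.config = config
        self.D = D
        self.n_labels = n_labels
        self.trained = False
        self.feature_clusters: list[int] | None = None  # preprocessing metadata
        self.input_space: str = "reduced"

        rng = np.random.default_rng(seed)
        L, Lc = config.L, config.L_c
        self.E_b = nn.mlp([D, 512, 256, L], rng)
        self.E_c = nn.mlp([D, 128, 64, Lc], rng)
        self.decoder = nn.mlp(
            [L + Lc, 256, 512, D], rng, hidden_activation=not config.linear_decoder
        )
        self.D_a = nn.mlp([L + Lc, 32, 32, 1], rng, hidden_batchnorm=False)
        self.D_b = nn.mlp([L, config.db_width, n_labels], rng, hidden_batchnorm=False)
        self.drop_b = nn.Dropout(config.dropout, rng)
        self.drop_c = nn.Dropout(config.conf_dropout, rng)
        self._rng = rng
        # per-feature standardization absorbed into the model: fitted on the
        # training matrix so optimization starts from a unit-scale problem
        self.x_mean = np.zeros(D, dtype=nn.DTYPE)
        self.x_sd = np.ones(D, dtype=nn.DTYPE)

    def fit_scaler(self, X: np.ndarray) -> None:
        X = np.asarray(X, dtype=np.float64)
        self.x_mean = X.mean(axis=0).astype(nn.DTYPE)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.x_sd = sd.astype(nn.DTYPE)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, nn.DTYPE) - self.x_mean) / self.x_sd

    def unstandardize(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.x_sd + self.x_mean

    # -- forward passes ------------------------------------------------------

    def _check_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim != 2 or X.shape[1] != self.D:
            raise ValueError(f"expected n x {self.D} input, got shape {X.shape}")
        return X

    def encode_arrays(self, X: np.ndarray, training: bool = False):
        """Raw (z_b, z_c) float32 arrays.

        Bottleneck dropout is applied downstream on the reconstruction path
        (see training), not here, so the discriminators always see clean
        latents.
        """
        X = self.standardize(self._check_features(X))
        zb = self.E_b.forward(X, training)
        zc = self.E_c.forward(X, training)
        return zb, zc

    def decode_arrays(self, zb: np.ndarray, zc: np.ndarray, training: bool = False):
        z = np.concatenate(
            [np.asarray(zb, nn.DTYPE), np.asarray(zc, nn.DTYPE)], axis=1
        )
        if z.shape[1] != self.config.L + self.config.L_c:
            raise ValueError(
                f"latent dims {z.shape[1]} do not match model "
                f"({self.config.L}+{self.config.L_c})"
            )
        return self.decoder.forward(z, training)

    def networks(self) -> dict[str, nn.Sequential]:
        return {
            "E_b": self.E_b,
            "E_c": self.E_c,
            "decoder": self.decoder,
            "D_a": self.D_a,
            "D_b": self.D_b,
        }

    # -- checkpoint plumbing -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"scaler.x_mean": self.x_mean, "scaler.x_sd": self.x_sd}
        for net_name, net in self.networks().items():
            for name, val, _ in net.parameters():
                state[f"{net_name}.{name}"] = val
            for name, val in net.buffers():
                state[f"{net_name}.buf.{name}"] = val
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("checkpoint parameter names do not match architecture")
        for name, arr in state.items():
            if own[name].shape != arr.shape:
                raise ValueError(
                    f"dimension mismatch for {name}: checkpoint {arr.shape} "
                    f"vs model {own[name].shape}"
                )
            own[name][...] = arr


def init_model(config: USADAEConfig, D: int, n_labels: int, seed: int | None = None) -> USADAEModel:
    """Build a model with reproducible parameter initialization."""
    return USADAEModel(config, D, n_labels, config.seed if seed is None else seed)


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ExpressionMatrix):
        return X.values, X.sample_ids
    X = np.asarray(X)
    return X, [str(i) for i in range(X.shape[0])]


def encode(model: USADAEModel, X) -> LatentPair:
    """Eval-mode encoding of an expression matrix into (Zb, Zc)."""
    values, sample_ids = _as_array(X)
    zb, zc = model.encode_arrays(values, training=False)
    return LatentPair(zb, zc, sample_ids)


def decode(model: USADAEModel, pair: LatentPair) -> ExpressionMatrix:
    """Eval-mode reconstruction from a latent pair."""
    xhat = model.unstandardize(model.decode_arrays(pair.Zb, pair.Zc, training=False))
    ids = pair.sample_ids or [str(i) for i in range(xhat.shape[0])]
    return ExpressionMatrix(
        xhat.astype(np.float64), ids, [f"f{j}" for j in range(model.D)], model.input_space
    )


def discriminate_joint(model: USADAEModel, pair: LatentPair) -> np.ndarray:
    """P(joint pairing) per sample from the independence discriminator."""
    z = np.concatenate(
        [np.asarray(pair.Zb, nn.DTYPE), np.asarray(pair.Zc, nn.DTYPE)], axis=1
    )
    if z.shape[1] != model.config.L + model.config.L_c:
        raise ValueError("latent dimensions do not match the discriminator input")
    logits = model.D_a.forward(z, False)
    return nn.sigmoid(logits.astype(np.float64)).ravel()


def classify_labels(model: USADAEModel, Zb: np.ndarray) -> np.ndarray:
    """Label probabilities from the biological latent; rows sum to 1."""
    Zb = np.asarray(Zb, nn.DTYPE)
    if Zb.ndim != 2 or Zb.shape[1] != model.config.L:
        raise ValueError(f"expected n x {model.config.L} biological latent")
    return nn.softmax(model.D_b.forward(Zb, False).astype(np.float64))


def correct_expression(
    model: USADAEModel, X, mode: Literal["mean", "zero"] | None = None
) -> ExpressionMatrix:
    """Confounder-corrected reconstruction.

    Every sample's z_c is replaced by the cohort column mean (default) or by
    zeros, so reconstruction retains biological variation while removing
    between-sample confounder variation.
    """
    if not model.trained:
        warnings.warn("correcting expression with an untrained model")
    mode = mode or model.config.correction
    values, sample_ids = _as_array(X)
    pair = encode(model, X)
    if mode == "mean":
        zc = np.broadcast_to(pair.Zc.mean(axis=0), pair.Zc.shape)
    elif mode == "zero":
        zc = np.zeros_like(pair.Zc)
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    xhat = model.unstandardize(model.decode_arrays(pair.Zb, zc, training=False)).astype(np.float64)
    feature_ids = (
        X.feature_ids if isinstance(X, ExpressionMatrix) else [f"f{j}" for j in range(model.D)]
    )
    space = X.space if isinstance(X, ExpressionMatrix) else model.input_space
    return ExpressionMatrix(xhat, sample_ids, feature_ids, space)
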