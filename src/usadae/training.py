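"""Losses and the three-stage adversarial training schedule.

Stage 1 trains the autoencoder alone (reconstruction MSE on standardized
features).  Stage 2 adds the independence game: the discriminator D_a
learns to tell joint latent pairings [z_b; z_c] from pairings with
row-shuffled z_c, while the encoders are driven to fool it (non-saturating,
flipped-label binary cross-entropy).  Stage 3 adds the cooperative label
term: the small discriminator D_b and the biological encoder jointly
descend a categorical cross-entropy on the condition/tissue label so z_b
retains biological signal.

Balance of the minimax game matters more than raw step counts: D_a takes
``adv_steps`` Adam updates (lr_adv) on detached latents before each encoder
update so it stays near its optimum, and the encoders receive deliberately
damped fool gradients (``bio_fool_scale`` / ``conf_fool_scale``) so the
factor partition settles instead of oscillating.  See docs/methods.md for
the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .data_io import ExpressionMatrix
from .model_core import USADAEConfig, USADAEModel

__all__ = [
    "TrainingHistory",
    "reconstruction_loss",
    "shuffle_confounders",
    "adversarial_losses",
    "tissue_loss",
    "train",
]


@dataclass
class TrainingHistory:
    """Per-epoch loss records across the three stages."""

    records: list[dict] = field(default_factory=list)

    def append(self, **rec) -> None:
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def stage_lengths(self) -> tuple[int, int, int]:
        stages = [r["stage"] for r in self.records]
        return (stages.count(1), stages.count(2), stages.count(3))


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean squared error over all n * D entries."""
    X = np.asarray(X, dtype=np.float64)
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    return float(np.mean((X - Xhat) ** 2))


def _draw_shuffle_perm(n: int, rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Uniform permutation resampled until at most ceil(n/10) fixed points.

    Honors the i != j pairing requirement in expectation without the cost of
    drawing exact derangements.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to shuffle confounder rows")
    limit = -(-n // 10)  # ceil(n/10)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if int((perm == np.arange(n)).sum()) <= limit:
            return perm
    return perm  # pragma: no cover — vanishing probability for n >= 2


def shuffle_confounders(Zc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-permuted copy of Zc used to build the 'shuffled' pairing."""
    Zc = np.asarray(Zc)
    return Zc[_draw_shuffle_perm(Zc.shape[0], rng)]


def adversarial_losses(
    model: USADAEModel, Zb: np.ndarray, Zc: np.ndarray, rng: np.random.Generator
) -> tuple[float, float]:
    """(discriminator loss, encoder fool loss) for the independence game.

    loss_Da is the BCE of D_a called with label 1 on joint pairings and 0 on
    shuffled pairings (ln 2 at maximal confusion, -> 0 at perfect
    separation).  loss_fool is the same BCE with flipped labels — the
    non-saturating objective the encoders descend.
    """
    Zb = np.asarray(Zb, nn.DTYPE)
    Zc = np.asarray(Zc, nn.DTYPE)
    if Zb.shape[0] < 2:
        raise ValueError("adversarial losses need at least 2 samples")
    Zc_shuf = shuffle_confounders(Zc, rng)
    stacked = np.concatenate(
        [np.concatenate([Zb, Zc], axis=1), np.concatenate([Zb, Zc_shuf], axis=1)], axis=0
    )
    logits = model.D_a.forward(stacked, False)
    n = Zb.shape[0]
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    loss_da, _ = nn.bce_with_logits(logits, labels)
    loss_fool, _ = nn.bce_with_logits(logits, 1.0 - labels)
    return loss_da, loss_fool


def tissue_loss(model: USADAEModel, Zb: np.ndarray, y_t: np.ndarray) -> float:
    """Mean categorical cross-entropy of the label discriminator on z_b."""
    y_t = np.asarray(y_t)
    if y_t.min() < 0 or y_t.max() >= model.n_labels:
        raise ValueError(
            f"label index outside [0, {model.n_labels}): saw {sorted(set(y_t.tolist()))}"
        )
    logits = model.D_b.forward(np.asarray(Zb, nn.DTYPE), False)
    loss, _ = nn.softmax_cross_entropy(logits, y_t)
    return loss


def _validate_labels(y: np.ndarray) -> tuple[np.ndarray, int]:
    y = np.asarray(y)
    if y.dtype.kind not in "iu":
        uniq, y = np.unique(y, return_inverse=True)
        return y.astype(np.int64), len(uniq)
    if y.min() < 0:
        raise ValueError("label indices must be non-negative")
    return y.astype(np.int64), int(y.max()) + 1


def train(
    model: USADAEModel,
    X,
    y_t,
    config: USADAEConfig | None = None,
    epoch_callback=None,
) -> tuple[USADAEModel, TrainingHistory]:
    """Run the three-stage schedule in place; returns (model, history).

    Fully reproducible given ``config.seed``: sample order, shuffle
    permutations and bottleneck dropout all derive from it.
    """
    config = config or model.config
    if isinstance(X, ExpressionMatrix):
        model.input_space = X.space
        X = X.values
    X = np.asarray(X, dtype=nn.DTYPE)
    y, n_seen = _validate_labels(y_t)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {y.shape[0]} labels")
    if n_seen > model.n_labels:
        raise ValueError(f"saw {n_seen} label levels but model has n_labels={model.n_labels}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("training needs at least 2 samples")
    model.fit_scaler(X)  # reconstruction happens on unit-scale features

    rng = np.random.default_rng(config.seed)
    model._rng = np.random.default_rng(config.seed + 1)  # bottleneck dropout stream
    model.drop_b.rng = model._rng
    model.drop_c.rng = model._rng

    ae_params = (
        model.E_b.parameters() + model.E_c.parameters() + model.decoder.parameters()
    )
    opt_ae = nn.Adam(ae_params, lr=config.lr_ae)
    opt_da = nn.Adam(model.D_a.parameters(), lr=config.lr_adv)
    opt_db = nn.Adam(model.D_b.parameters(), lr=config.lr_tissue)

    L = config.L
    history = TrainingHistory()
    bs = config.batch_size
    lam_adv, lam_tis = config.lambda_adv, config.lambda_tissue
    epoch_global = 0

    for stage in (1, 2, 3):
        for _ in range(config.epochs[stage - 1]):
            epoch_global += 1
            if stage >= 2 and config.critic_mode == "epoch":
                _critic_epoch(model, opt_da, X, rng)
            order = rng.permutation(n)
            sums = {"recon": 0.0, "da": 0.0, "fool": 0.0, "tissue": 0.0}
            counts = 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                if idx.size < 2:
                    continue  # a singleton batch breaks batch-norm and shuffling
                xb, yb = X[idx], y[idx]
                step = _train_step(
                    model, opt_ae, opt_da, opt_db, xb, yb, stage, rng, lam_adv, lam_tis, L
                )
                for k, v in step.items():
                    sums[k] += v
                counts += 1
            means = {k: (v / counts if counts else np.nan) for k, v in sums.items()}
            if not np.isfinite(means["recon"]):
                raise RuntimeError(
                    f"non-finite reconstruction loss at stage {stage}, epoch {epoch_global}"
                )
            if epoch_callback is not None:
                epoch_callback(model, stage, epoch_global)
            history.append(
                epoch=epoch_global,
                stage=stage,
                recon=means["recon"],
                loss_da=means["da"] if stage >= 2 else None,
                loss_fool=means["fool"] if stage >= 2 else None,
                loss_tissue=means["tissue"] if stage >= 3 else None,
                lambda_adv=lam_adv if stage >= 2 else None,
                lambda_tissue=lam_tis if stage >= 3 else None,
            )
    model.trained = True
    return model, history


def _critic_epoch(model, opt_da, X, rng):
    """Epoch-level D_a training on full-dataset latents.

    The independence signal is a population property; estimating it on the
    whole cohort (rather than only 128-sample mini-batches) keeps the
    discriminator near its optimum while the encoders drift.  D_a is tiny,
    so ``adv_steps`` full-batch steps cost almost nothing.
    """
    zb, zc = model.encode_arrays(X, training=False)
    n = zb.shape[0]
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    for _ in range(model.config.adv_steps):
        model.D_a.zero_grad()
        perm = _draw_shuffle_perm(n, rng)
        stacked = np.concatenate(
            [
                np.concatenate([zb, zc], axis=1),
                np.concatenate([zb, zc[perm]], axis=1),
            ],
            axis=0,
        )
        logits = model.D_a.forward(stacked, True)
        _, g_logit = nn.bce_with_logits(logits, labels)
        model.D_a.backward(g_logit)
        opt_da.step()


def _train_step(model, opt_ae, opt_da, opt_db, xb, yb, stage, rng, lam_adv, lam_tis, L):
    """One mini-batch: encoder/decoder (+D_b) update, then a D_a update."""
    nb = xb.shape[0]
    for net in model.networks().values():
        net.zero_grad()

    # encoder forward; bottleneck dropout corrupts only the decoder input
    zb, zc = model.encode_arrays(xb, training=True)

    # discriminator update(s) on this batch's detached latents, before the
    # encoders see the fool gradient
    da = 0.0
    if stage >= 2:
        n_steps = 1 if model.config.critic_mode == "epoch" else model.config.adv_steps
        labels = np.concatenate([np.ones(nb), np.zeros(nb)])
        for _ in range(n_steps):
            model.D_a.zero_grad()
            perm2 = _draw_shuffle_perm(nb, rng)
            stacked = np.concatenate(
                [
                    np.concatenate([zb, zc], axis=1),
                    np.concatenate([zb, zc[perm2]], axis=1),
                ],
                axis=0,
            )
            logits = model.D_a.forward(stacked, True)
            da, g_logit = nn.bce_with_logits(logits, labels)
            model.D_a.backward(g_logit)
            opt_da.step()

    zbd = model.drop_b.forward(zb, True)
    zcd = model.drop_c.forward(zc, True)
    xhat = model.decoder.forward(np.concatenate([zbd, zcd], axis=1), True)

    diff = (xhat - model.standardize(xb)).astype(np.float64)
    recon = float(np.mean(diff * diff))
    g_dec_out = (2.0 / diff.size * diff).astype(nn.DTYPE)
    g_z = model.decoder.backward(g_dec_out)
    g_zb = model.drop_b.backward(g_z[:, :L].copy())
    g_zc = model.drop_c.backward(g_z[:, L:].copy())

    fool = tis = 0.0
    perm = None
    if stage >= 2:
        perm = _draw_shuffle_perm(nb, rng)
        stacked = np.concatenate(
            [
                np.concatenate([zb, zc], axis=1),
                np.concatenate([zb, zc[perm]], axis=1),
            ],
            axis=0,
        )
        logits = model.D_a.forward(stacked, True)
        labels = np.concatenate([np.ones(nb), np.zeros(nb)])
        fool, g_logit = nn.bce_with_logits(logits, 1.0 - labels)  # flipped labels
        g_stacked = model.D_a.backward(g_logit * np.float32(lam_adv))
        g_joint, g_shuf = g_stacked[:nb], g_stacked[nb:]
        cfs = np.float32(model.config.conf_fool_scale)
        bfs = np.float32(model.config.bio_fool_scale)
        g_zb += bfs * (g_joint[:, :L] + g_shuf[:, :L])
        g_zc += cfs * g_joint[:, L:]
        np.add.at(g_zc, perm, cfs * g_shuf[:, L:])

    if stage >= 3:
        logits_b = model.D_b.forward(zb, True)
        tis, g_tis = nn.softmax_cross_entropy(logits_b, yb)
        g_zb += model.D_b.backward(g_tis * np.float32(lam_tis))

    model.E_b.backward(g_zb.astype(nn.DTYPE))
    model.E_c.backward(g_zc.astype(nn.DTYPE))
    opt_ae.step()
    if stage >= 3:
        opt_db.step()

    return {"recon": recon, "da": da, "fool": fool, "tissue": tis}
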