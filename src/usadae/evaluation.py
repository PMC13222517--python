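"""Evaluation harnesses: covariate recovery by cross-validated prediction,
DEA/eGene accuracy against simulation truth, cross-fold replication rates,
and a canonical-correlation permutation test of latent independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import (
    f1_score,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .downstream import DEAResult, EQTLResult, call_degs

__all__ = [
    "CVRecord",
    "ReplicationResult",
    "evaluate_covariate_prediction",
    "evaluate_dea",
    "evaluate_egene_detection",
    "replication_rate",
    "latent_independence_score",
]


@dataclass
class CVRecord:
    """Fold-wise scores for one (latent source, covariate) prediction task."""

    task: str  # classification | regression
    model_kind: str
    fold_scores: dict = field(default_factory=dict)  # metric -> list of fold values

    def mean(self, metric: str) -> float:
        return float(np.mean(self.fold_scores[metric]))

    def se(self, metric: str) -> float:
        v = np.asarray(self.fold_scores[metric], dtype=float)
        return float(v.std(ddof=1) / np.sqrt(v.size))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "mean": self.mean(m), "se": self.se(m),
             "folds": len(v), "task": self.task, "model": self.model_kind}
            for m, v in self.fold_scores.items()
        ]
        return pd.DataFrame(rows)


def _make_estimator(task: str, model_kind: str, seed: int):
    if task == "classification":
        if model_kind == "logistic":
            return make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
            )
        if model_kind == "random_forest":
            return RandomForestClassifier(n_estimators=200, random_state=seed)
        if model_kind == "svm":
            return make_pipeline(StandardScaler(), SVC(probability=True, random_state=seed))
    else:
        if model_kind == "linear":
            return LinearRegression()
        if model_kind == "random_forest":
            return RandomForestRegressor(n_estimators=200, random_state=seed)
        if model_kind == "svm":
            return make_pipeline(StandardScaler(), SVR())
    raise ValueError(f"unsupported model kind {model_kind!r} for task {task!r}")


def evaluate_covariate_prediction(
    Z: np.ndarray,
    target: np.ndarray,
    task: str,
    model_kind: str | None = None,
    folds: int = 5,
    seed: int = 0,
) -> CVRecord:
    """k-fold CV prediction of a known covariate from a latent (or covariate)
    matrix; stratified folds for classification.

    Classification reports AUC (one-vs-rest macro for >2 classes), macro or
    binary F1/precision/recall; regression reports held-out R2 (which may be
    negative and is not clipped).
    """
    Z = np.asarray(Z, dtype=float)
    target = np.asarray(target)
    if Z.shape[0] != target.shape[0]:
        raise ValueError("rows of Z and target are not aligned")
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    model_kind = model_kind or ("logistic" if task == "classification" else "linear")

    scores: dict[str, list] = {}
    if task == "classification":
        classes, y = np.unique(target, return_inverse=True)
        counts = np.bincount(y)
        if counts.min() < folds:
            raise ValueError(
                f"class with only {counts.min()} samples cannot appear in every "
                f"training fold; use fewer than {folds} folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        binary = len(classes) == 2
        avg = "binary" if binary else "macro"
        for tr, te in splitter.split(Z, y):
            est = _make_estimator(task, model_kind, seed)
            est.fit(Z[tr], y[tr])
            prob = est.predict_proba(Z[te])
            pred = np.argmax(prob, axis=1)
            if binary:
                auc = roc_auc_score(y[te], prob[:, 1])
            else:
                auc = roc_auc_score(y[te], prob, multi_class="ovr", average="macro")
            scores.setdefault("auc", []).append(auc)
            scores.setdefault("f1", []).append(f1_score(y[te], pred, average=avg, zero_division=0))
            scores.setdefault("precision", []).append(
                precision_score(y[te], pred, average=avg, zero_division=0)
            )
            scores.setdefault("recall", []).append(
                recall_score(y[te], pred, average=avg, zero_division=0)
            )
    else:
        y = target.astype(float)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in splitter.split(Z):
            est = _make_estimator(task, model_kind, seed)
            est.fit(Z[tr], y[tr])
            scores.setdefault("r2", []).append(r2_score(y[te], est.predict(Z[te])))
    return CVRecord(task=task, model_kind=model_kind, fold_scores=scores)


def evaluate_dea(res: DEAResult, truth: np.ndarray) -> dict:
    """ROC AUC from the p-value ranking plus dual-threshold F1/precision/recall."""
    truth = np.asarray(truth, dtype=bool)
    if truth.shape[0] != len(res.gene_ids):
        raise ValueError("truth length does not match result genes")
    out: dict[str, float | None] = {}
    if truth.all() or not truth.any():
        warnings.warn("degenerate truth (all one class): AUC undefined")
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(truth, -res.p_value))
    calls = call_degs(res)
    out["f1"] = float(f1_score(truth, calls, zero_division=0))
    out["precision"] = float(precision_score(truth, calls, zero_division=0))
    out["recall"] = float(recall_score(truth, calls, zero_division=0))
    return out


def evaluate_egene_detection(
    res: EQTLResult, truth: pd.DataFrame, h2_bins: list
) -> pd.DataFrame:
    """Per-h2-bin precision/recall/F1 of eGene calls.

    ``truth`` needs columns gene_id, egene (bool/int) and h2 (target value;
    0 for non-eGenes).  Genes the mapper could not test count as not called.
    """
    t = truth.set_index("gene_id")
    calls = dict(zip(res.genes["gene_id"], res.genes["egene"]))
    rows = []
    edges = list(h2_bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = t[(t["h2"] >= lo) & (t["h2"] < hi)]
        if len(in_bin) == 0:
            rows.append({"h2_lo": lo, "h2_hi": hi, "n": 0, "precision": np.nan,
                         "recall": np.nan, "f1": np.nan})
            continue
        y = in_bin["egene"].astype(bool).to_numpy()
        yhat = np.array([bool(calls.get(g, False)) for g in in_bin.index])
        tp = int((y & yhat).sum())
        prec = tp / yhat.sum() if yhat.sum() else np.nan
        rec = tp / y.sum() if y.sum() else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if prec == prec and rec == rec and (prec + rec) > 0 else np.nan)
        rows.append({"h2_lo": lo, "h2_hi": hi, "n": len(in_bin),
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows)


@dataclass
class ReplicationResult:
    """Cross-fold replication (pi) statistics for significant signal sets."""

    per_fold: pd.DataFrame  # fold, N, then n_k / pi_k for k = 1..folds-1

    def pi_means(self) -> dict:
        cols = [c for c in self.per_fold.columns if c.startswith("pi_")]
        return {c: float(self.per_fold[c].mean(skipna=True)) for c in cols}


def replication_rate(fold_sets: list) -> ReplicationResult:
    """pi_k per discovery fold: the fraction of its significant signals seen
    in at least k of the other folds' significant sets."""
    folds = len(fold_sets)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    sets = [set(s) for s in fold_sets]
    rows = []
    for d in range(folds):
        discovery = sets[d]
        others = [sets[i] for i in range(folds) if i != d]
        row: dict = {"fold": d, "N": len(discovery)}
        if not discovery:
            warnings.warn(f"fold {d}: empty discovery set, pi undefined")
            for k in range(1, folds):
                row[f"n_{k}"] = np.nan
                row[f"pi_{k}"] = np.nan
        else:
            counts = {sig: sum(sig in o for o in others) for sig in discovery}
            for k in range(1, folds):
                n_k = sum(c >= k for c in counts.values())
                row[f"n_{k}"] = n_k
                row[f"pi_{k}"] = n_k / len(discovery)
        rows.append(row)
    df = pd.DataFrame(rows)
    pis = df[[c for c in df.columns if c.startswith("pi_")]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        assert not (np.diff(pis, axis=1) > 1e-12).any(), "pi must be non-increasing in k"
    return ReplicationResult(df)


def _drop_constant(Z: np.ndarray, name: str) -> np.ndarray:
    keep = Z.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) from {name}")
    return Z[:, keep]


def _largest_canonical_correlation(A: np.ndarray, B: np.ndarray) -> float:
    Qa, _ = np.linalg.qr(A - A.mean(axis=0))
    Qb, _ = np.linalg.qr(B - B.mean(axis=0))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(min(s.max(), 1.0))


def latent_independence_score(
    Zb: np.ndarray, Zc: np.ndarray, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Largest canonical correlation between Zb and Zc with a row-permutation
    p-value (permuting Zc); large statistic + small p indicate dependence."""
    Zb = np.asarray(Zb, dtype=float)
    Zc = np.asarray(Zc, dtype=float)
    if Zb.shape[0] != Zc.shape[0]:
        raise ValueError("Zb and Zc rows are not aligned")
    if Zb.shape[0] < 20:
        raise ValueError("need at least 20 samples for a stable test")
    Zb = _drop_constant(Zb, "Zb")
    Zc = _drop_constant(Zc, "Zc")
    stat = _largest_canonical_correlation(Zb, Zc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Zc.shape[0])
        if _largest_canonical_correlation(Zb, Zc[perm]) >= stat:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return stat, p
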