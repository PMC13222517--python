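"""Covariate-adjusted differential expression and cis-eQTL mapping.

Both analyses consume extracted confounders (or any covariate matrix) as
nuisance regressors.  DEA fits per-gene ordinary least squares of log2
expression on [intercept, group, covariates]; the group coefficient is the
log2 fold change and its two-sided t test gives the p-value, adjusted by
Benjamini-Hochberg across genes.  The cis-eQTL mapper residualizes
expression and dosages on the covariates (Frisch-Waugh), fits per-pair
simple regressions within the TSS-anchored +/-1 Mb window, and calls eGenes
by Bonferroni-adjusted minimum p per gene followed by BH across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "DEAResult",
    "EQTLResult",
    "bh_adjust",
    "dea_linear",
    "call_degs",
    "map_cis_eqtl",
]

logger = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEAResult:
    gene_ids: list
    log2fc: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    p_adj: np.ndarray

    def __post_init__(self) -> None:
        if not (((self.p_value >= 0) & (self.p_value <= 1)).all()):
            raise ValueError("p-values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2fc": self.log2fc,
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "p_adj": self.p_adj,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _as_values(X) -> tuple[np.ndarray, list]:
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.feature_ids)
    X = np.asarray(X, dtype=float)
    return X, [f"g{j}" for j in range(X.shape[1])]


def _check_design(Z: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(Z.shape[1]):
            keep = [k for k in range(Z.shape[1]) if k != j]
            if np.linalg.matrix_rank(Z[:, keep]) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def dea_linear(X, group, covariates=None) -> DEAResult:
    """Per-gene OLS differential expression on log2-scale data.

    ``group`` is binary (0 = control, 1 = case); the fitted group
    coefficient is the log2FC.  Covariates, if given, enter the design
    untransformed.
    """
    Y, gene_ids = _as_values(X)
    group = np.asarray(group, dtype=float)
    n = Y.shape[0]
    if group.shape[0] != n:
        raise ValueError("group length does not match sample count")
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        cols.extend(C.T)
        names.extend(f"cov{j}" for j in range(C.shape[1]))
    Z = np.column_stack(cols)
    p_design = Z.shape[1]
    if n <= p_design:
        raise ValueError(f"n={n} samples cannot identify {p_design} coefficients")
    _check_design(Z, names)

    ZtZinv = np.linalg.inv(Z.T @ Z)
    beta = ZtZinv @ (Z.T @ Y)  # p_design x n_genes
    resid = Y - Z @ beta
    df = n - p_design
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * ZtZinv[1, 1], 1e-300))
    log2fc = beta[1]
    t = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return DEAResult(gene_ids, log2fc, t, p, bh_adjust(p))


def call_degs(res: DEAResult, p_adj_max: float = 0.05, fc_min: float = 0.263) -> np.ndarray:
    """Dual-threshold DEG call: adjusted p strictly below p_adj_max AND
    |log2FC| strictly above fc_min."""
    return (res.p_adj < p_adj_max) & (np.abs(res.log2fc) > fc_min)


@dataclass
class EQTLResult:
    pairs: pd.DataFrame  # gene_id, snp_id, distance, slope, se, p_nominal
    genes: pd.DataFrame  # gene_id, n_cis, best_snp, p_min, p_gene, p_adj, egene
    untestable: list

    def write(self, pairs_path, genes_path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def map_cis_eqtl(
    G: GenotypeMatrix,
    expr: ExpressionMatrix,
    tss,
    covariates=None,
    window_bp: int = 1_000_000,
    egene_fdr: float = 0.05,
    permutations: int = 0,
    seed: int = 0,
) -> EQTLResult:
    """Nominal-pass cis-eQTL scan with covariate residualization.

    The cis window is inclusive: |SNP position - TSS| <= window_bp, 1-based
    coordinates.  Gene-level p is Bonferroni (min nominal p x number of
    tested cis SNPs, capped at 1); eGenes are BH < ``egene_fdr`` across
    testable genes.  With ``permutations`` > 0 the gene-level p is instead
    estimated by permuting expression rows.
    """
    if G.sample_ids != expr.sample_ids:
        raise ValueError("genotype and expression sample ids are not aligned")
    tss = np.asarray(tss, dtype=np.int64)
    if tss.shape[0] != expr.n_features:
        raise ValueError("one TSS per gene required")
    n = G.n_samples
    Zcols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Zcols.extend(C.T)
        names.extend(f"cov{j}" for j in range(C.shape[1]))
    Z = np.column_stack(Zcols)
    _check_design(Z, names)
    n_cov = Z.shape[1] - 1
    df = n - n_cov - 2
    if df <= 0:
        raise ValueError("not enough samples for the covariate count")

    order = np.argsort(G.positions, kind="stable")
    pos_sorted = G.positions[order]
    dos = G.dosages.astype(np.float64)[:, order]
    snp_ids_sorted = [G.snp_ids[i] for i in order]

    mono = dos.std(axis=0) == 0
    if mono.any():
        logger.info("skipping %d monomorphic SNPs", int(mono.sum()))

    Yr = _residualize(expr.values, Z)
    Dr = _residualize(dos, Z)

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(permutations)]

    pair_rows = []
    gene_rows = []
    untestable = []
    for j, gene in enumerate(expr.feature_ids):
        lo = np.searchsorted(pos_sorted, tss[j] - window_bp, side="left")
        hi = np.searchsorted(pos_sorted, tss[j] + window_bp, side="right")
        idx = np.arange(lo, hi)
        idx = idx[~mono[idx]]
        if idx.size == 0:
            untestable.append(gene)
            continue
        Xr = Dr[:, idx]
        yr = Yr[:, j]
        sxx = (Xr**2).sum(axis=0)
        sxy = Xr.T @ yr
        slope = sxy / sxx
        rss = (yr**2).sum() - slope * sxy
        sigma2 = np.maximum(rss / df, 1e-300)
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        best = int(np.argmin(p))
        if permutations > 0:
            p_obs = p[best]
            count = 0
            for perm in perms:
                yp = yr[perm]
                sl = (Xr.T @ yp) / sxx
                rssp = (yp**2).sum() - sl * (Xr.T @ yp)
                tp = sl / np.sqrt(np.maximum(rssp / df, 1e-300) / sxx)
                pp = 2.0 * stats.t.sf(np.abs(tp), df)
                if pp.min() <= p_obs:
                    count += 1
            p_gene = (1 + count) / (1 + permutations)
        else:
            p_gene = min(p[best] * idx.size, 1.0)
        for k, s in enumerate(idx):
            pair_rows.append(
                (gene, snp_ids_sorted[s], int(pos_sorted[s] - tss[j]), slope[k], se[k], p[k])
            )
        gene_rows.append((gene, idx.size, snp_ids_sorted[idx[best]], p[best], p_gene))

    pairs = pd.DataFrame(
        pair_rows, columns=["gene_id", "snp_id", "distance", "slope", "se", "p_nominal"]
    )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "n_cis", "best_snp", "p_min", "p_gene"]
    )
    if len(genes):
        genes["p_adj"] = bh_adjust(genes["p_gene"].to_numpy())
        genes["egene"] = genes["p_adj"] < egene_fdr
    else:
        genes["p_adj"] = np.array([], dtype=float)
        genes["egene"] = np.array([], dtype=bool)
    return EQTLResult(pairs, genes, untestable)
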