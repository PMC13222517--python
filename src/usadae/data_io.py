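"""Reading and writing expression matrices, covariate tables, genotypes and
model checkpoints.

All tabular formats are tab-separated UTF-8 text with a ``.`` decimal point,
one header row of ids and the first column holding row ids.  Missing values
are hard errors: the model has no missingness mechanism, so nothing is
imputed silently.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "GenotypeMatrix",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_genotypes",
    "write_genotypes",
    "read_vcf_genotypes",
    "save_model",
    "load_model",
]

Space = Literal["counts", "tpm", "log2", "reduced"]
VALID_SPACES = ("counts", "tpm", "log2", "reduced")

#: float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """A samples x features real matrix with a tag for the value space.

    ``space`` records what the numbers mean: raw ``counts``, ``tpm``,
    ``log2``-transformed values, or ``reduced`` (cluster-averaged features
    produced by the k-means++ reduction).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    space: Space

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.space not in VALID_SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {VALID_SPACES}")
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_ids, "feature ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if self.space == "counts" and (self.values < 0).any():
            raise ValueError("space='counts' requires non-negative values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        cols = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.sample_ids), list(feature_ids), self.space
        )


@dataclass
class CovariateTable:
    """Per-sample covariates; each column is tagged categorical or continuous."""

    sample_ids: list[str]
    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)  # column -> {categorical, continuous}

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample ids")
        if len(self.data) != len(self.sample_ids):
            raise ValueError("covariate table row count does not match sample ids")
        self.data = self.data.copy()
        self.data.index = pd.Index(self.sample_ids)
        for col, kind in self.kinds.items():
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"column {col!r}: unknown kind {kind!r}")
            if kind == "categorical":
                if self.data[col].nunique() < 2:
                    raise ValueError(f"categorical column {col!r} has <2 observed levels")
            else:
                vals = pd.to_numeric(self.data[col])
                if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                    raise ValueError(f"continuous column {col!r} has non-finite values")

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2) with genomic coordinates and MAF."""

    dosages: np.ndarray  # n_samples x n_snps, entries in {0,1,2}
    sample_ids: list[str]
    snp_ids: list[str]
    chromosome: list[str]
    positions: np.ndarray  # 1-based bp
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.dosages, (0, 1, 2)))[0]
            raise ValueError(
                f"dosage outside {{0,1,2}} at sample row {bad[0]}, SNP column {bad[1]}"
            )
        self.dosages = self.dosages.astype(np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample id count does not match dosage rows")
        if not (len(self.snp_ids) == len(self.chromosome) == len(self.positions) == len(self.maf) == m):
            raise ValueError("SNP annotation lengths do not match dosage columns")
        _check_unique(self.snp_ids, "SNP ids")
        if (self.positions < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if ((self.maf < 0) | (self.maf > 0.5)).any():
            raise ValueError("maf must lie in [0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.dosages[:, keep],
            list(self.sample_ids),
            [self.snp_ids[i] for i in keep],
            [self.chromosome[i] for i in keep],
            self.positions[keep],
            self.maf[keep],
        )


# ---------------------------------------------------------------------------
# expression I/O


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # pandas silently renames duplicate header entries, so check them raw
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column ids")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    return df


def read_expression(
    path: str | Path,
    orientation: Literal["samples_in_rows", "genes_in_rows"] = "samples_in_rows",
    space: Space = "log2",
) -> ExpressionMatrix:
    """Read a delimited expression table, returning it oriented samples x features.

    Raises on duplicate ids, non-numeric cells and missing values — no silent
    imputation.
    """
    raw = _read_tsv(path)
    _check_unique(list(map(str, raw.index)), "row ids")
    _check_unique(list(map(str, raw.columns)), "column ids")
    values = np.empty(raw.shape, dtype=np.float64)
    for j, col in enumerate(raw.columns):
        try:
            # numpy's parser is correctly rounded (pandas' fast path is not)
            values[:, j] = raw[col].to_numpy(dtype="U32").astype(np.float64)
        except (ValueError, TypeError) as exc:
            bad = [i for i, v in enumerate(raw[col]) if not _is_number(v)]
            row = raw.index[bad[0]] if bad else "?"
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at row {raw.index[i]!r}, column {raw.columns[j]!r}")
    if orientation == "genes_in_rows":
        values = values.T
        sample_ids, feature_ids = list(raw.columns), list(raw.index)
    else:
        sample_ids, feature_ids = list(raw.index), list(raw.columns)
    return ExpressionMatrix(values, [str(s) for s in sample_ids], [str(f) for f in feature_ids], space)


def _is_number(v) -> bool:
    if v is None:
        return False
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write samples-in-rows TSV; floats at 17 significant digits (lossless)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(x.feature_ids) + "\n")
        for i, sid in enumerate(x.sample_ids):
            row = "\t".join(_FLOAT_FMT % v for v in x.values[i])
            fh.write(f"{sid}\t{row}\n")


def read_covariates(path: str | Path, kinds: Mapping[str, str] | None = None) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.isna().any().any():
        raise ValueError(f"missing value in covariate table {path}")
    kinds = dict(kinds) if kinds else _infer_kinds(df)
    return CovariateTable([str(s) for s in df.index], df, kinds)


def _infer_kinds(df: pd.DataFrame) -> dict[str, str]:
    kinds = {}
    for col in df.columns:
        vals = df[col]
        if vals.dtype.kind in "ifu" and vals.nunique() > 10:
            kinds[col] = "continuous"
        else:
            kinds[col] = "categorical"
    return kinds


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# genotype I/O


def empirical_maf(dosages: np.ndarray) -> np.ndarray:
    """MAF per SNP as min(p, 1-p) with p = mean(dosage)/2."""
    p = np.asarray(dosages, dtype=np.float64).mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def read_genotypes(
    path: str | Path,
    map_path: str | Path,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Read a TSV dosage matrix (sample rows, SNP columns) plus a SNP map
    (columns: snp_id, chromosome, position); drop SNPs with empirical
    MAF < ``maf_min`` and recompute MAF from the dosages."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    snp_map = snp_map.set_index("snp_id")
    missing = [s for s in df.columns if s not in snp_map.index]
    if missing:
        raise ValueError(f"SNPs missing from map: {missing[:10]}")
    dosages = df.to_numpy()
    if not np.isin(dosages, (0, 1, 2)).all():
        i, j = np.argwhere(~np.isin(dosages, (0, 1, 2)))[0]
        raise ValueError(
            f"dosage outside {{0,1,2}} at sample {df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    maf = empirical_maf(dosages)
    keep = np.flatnonzero(maf >= maf_min)
    snp_ids = [str(df.columns[j]) for j in keep]
    return GenotypeMatrix(
        dosages[:, keep],
        [str(s) for s in df.index],
        snp_ids,
        [str(snp_map.loc[s, "chromosome"]) for s in snp_ids],
        snp_map.loc[snp_ids, "position"].to_numpy(dtype=np.int64),
        maf[keep],
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )
    pd.DataFrame(
        {"snp_id": g.snp_ids, "chromosome": g.chromosome, "position": g.positions}
    ).to_csv(map_path, sep="\t", index=False)


def read_vcf_genotypes(path: str | Path, maf_min: float = 0.05) -> GenotypeMatrix:
    """Import biallelic GT records from a VCF as alt-allele dosages.

    Multi-allelic records are an error; missing genotypes are an error.
    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # lazy: optional extra

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, snp_ids, chroms, positions = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        gt = np.asarray(rec.genotype.array())[:, :2]
        if (gt < 0).any():
            raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        cols.append(gt.sum(axis=1))
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        positions.append(rec.POS)
    dosages = np.stack(cols, axis=1)
    maf = empirical_maf(dosages)
    keep = maf >= maf_min
    g = GenotypeMatrix(
        dosages, sample_ids, snp_ids, chroms, np.asarray(positions), maf
    )
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# model checkpoints
#
# Single-file zip archive: config.json (model config + preprocessing metadata)
# and one little-endian .npy blob per parameter/buffer.


def save_model(model, path: str | Path) -> None:
    """Persist a fitted model: JSON config block plus binary parameter blobs."""
    state = model.state_dict()
    meta = {
        "format": "usadae-checkpoint-v1",
        "config": model.config.to_dict(),
        "D": model.D,
        "n_labels": model.n_labels,
        "trained": model.trained,
        "feature_clusters": model.feature_clusters,
        "params": sorted(state),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("config.json", json.dumps(meta, indent=1))
        for name, arr in state.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_model(path: str | Path):
    """Load a checkpoint written by :func:`save_model`."""
    from .model_core import USADAEConfig, init_model

    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("config.json"))
        if meta.get("format") != "usadae-checkpoint-v1":
            raise ValueError(f"{path}: not a usadae checkpoint")
        config = USADAEConfig.from_dict(meta["config"])
        model = init_model(config, D=meta["D"], n_labels=meta["n_labels"], seed=config.seed)
        state = {}
        for name in meta["params"]:
            state[name] = np.load(io.BytesIO(zf.read(f"params/{name}.npy")))
        model.load_state_dict(state)
        model.trained = meta["trained"]
        model.feature_clusters = meta["feature_clusters"]
    return model
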