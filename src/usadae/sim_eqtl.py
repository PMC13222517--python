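"""Multi-tissue cis-eQTL simulation with known eGenes and heritabilities.

Genotypes are binomial draws at per-SNP minor-allele frequencies (no real
panel is required; linkage disequilibrium is absent by default, with an
optional Markov-neighbor LD mode).  For each eGene and tissue, 5-15 causal
SNPs within 1 Mb of the TSS receive normal effects scaled by
[2 MAF (1-MAF)]^(-1/2) (the GCTA alpha = -1 convention), and expression is
assembled on a unit-variance budget: sqrt(h2) x standardized genetic value
+ confounder signal + residual noise, so the realized cis-heritability
tracks its target in [0.005, 0.80].  Confounders (batch, age, sex, with
quadratic-age and batch x sex terms) enter the same way as in the
differential-expression simulator.  Sharing structure: shared eGenes reuse
one causal set in every tissue, tissue-specific eGenes get a different set
per tissue, unique eGenes appear in a single tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    empirical_maf,
    write_covariates,
    write_expression,
    write_genotypes,
)

__all__ = [
    "EQTLSimConfig",
    "SimulatedEQTLDataset",
    "simulate_genotypes",
    "simulate_eqtl_dataset",
]

DEFAULT_H2_GRID = [0.005, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8]


@dataclass
class EQTLSimConfig:
    n_genes: int = 2000
    n_tissues: int = 3
    n_snps: int = 10_000
    n_samples: int = 500
    maf_min: float = 0.01
    h2_grid: list = field(default_factory=lambda: list(DEFAULT_H2_GRID))
    frac_egenes: float = 0.5
    sharing_proportions: tuple = (0.4, 0.3, 0.3)  # shared, tissue_specific, unique
    causal_range: tuple = (5, 15)
    window_bp: int = 1_000_000
    region_length: int = 50_000_000
    confounder_var: float = 0.15  # variance fraction of the confounder signal
    frac_affected: float = 0.5
    noise_scale: tuple = (1.0, 1.0, 1.0)  # per-tissue residual multiplier
    ld_rho: float = 0.0  # Markov-neighbor haplotype correlation, 0 = none
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "n_snps", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if any(h <= 0 or h >= 1 for h in self.h2_grid):
            raise ValueError("h2 values must lie in (0, 1)")
        if abs(sum(self.sharing_proportions) - 1.0) > 1e-9:
            raise ValueError("sharing proportions must sum to 1")
        if max(self.h2_grid) + self.confounder_var >= 1.0:
            raise ValueError(
                f"h2 + confounder variance must stay below 1 "
                f"(max h2 {max(self.h2_grid)} + {self.confounder_var})"
            )
        if len(self.noise_scale) != self.n_tissues:
            raise ValueError("noise_scale needs one entry per tissue")


@dataclass
class SimulatedEQTLDataset:
    genotypes: GenotypeMatrix
    expression: dict  # tissue -> ExpressionMatrix
    gene_positions: np.ndarray  # TSS, 1-based bp
    gene_ids: list
    causal_sets: dict  # (gene_id, tissue) -> list of (snp_id, beta)
    h2: dict  # (gene_id, tissue) -> target cis-h2
    egene_truth: dict  # (gene_id, tissue) -> bool
    covariates: CovariateTable
    tissue_sharing: dict  # gene_id -> {shared, tissue_specific, unique, none}
    genetic_values: dict  # tissue -> n_samples x n_genes standardized genetic values
    config: EQTLSimConfig

    @property
    def tissues(self) -> list:
        return list(self.expression)

    def stacked_expression(self) -> tuple[ExpressionMatrix, np.ndarray]:
        """All tissues stacked into one matrix (sample ids suffixed by
        tissue) with the integer tissue label per row — the model's
        multi-tissue training input."""
        blocks, ids, labels = [], [], []
        for t_idx, (tissue, mat) in enumerate(self.expression.items()):
            blocks.append(mat.values)
            ids.extend(f"{s}:{tissue}" for s in mat.sample_ids)
            labels.extend([t_idx] * mat.n_samples)
        stacked = ExpressionMatrix(
            np.vstack(blocks), ids, list(self.gene_ids), "log2"
        )
        return stacked, np.asarray(labels)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, outdir / "dosages.tsv", outdir / "snp_map.tsv")
        for tissue, mat in self.expression.items():
            write_expression(mat, outdir / f"expression_{tissue}.tsv")
        write_covariates(self.covariates, outdir / "covariates.tsv")
        pd.DataFrame(
            {"gene_id": self.gene_ids, "tss": self.gene_positions}
        ).to_csv(outdir / "gene_positions.tsv", sep="\t", index=False)
        rows = []
        for (gene, tissue), is_egene in self.egene_truth.items():
            rows.append(
                {
                    "gene_id": gene,
                    "tissue": tissue,
                    "egene": int(is_egene),
                    "h2": self.h2.get((gene, tissue), 0.0),
                    "n_causal": len(self.causal_sets.get((gene, tissue), [])),
                    "sharing": self.tissue_sharing.get(gene, "none"),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {"generator": "simulate_eqtl_dataset", "config": asdict(self.config)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def simulate_genotypes(config: EQTLSimConfig) -> GenotypeMatrix:
    """Binomial(2, MAF) dosages with MAF ~ Uniform(maf_min, 0.5) per SNP and
    sorted uniform positions on one chromosome; MAF recorded empirically."""
    rng = np.random.default_rng(config.seed)
    maf = rng.uniform(config.maf_min, 0.5, size=config.n_snps)
    positions = np.sort(
        rng.choice(config.region_length, size=config.n_snps, replace=False) + 1
    )
    if config.ld_rho > 0:
        hap1 = _markov_haplotypes(maf, config.n_samples, config.ld_rho, rng)
        hap2 = _markov_haplotypes(maf, config.n_samples, config.ld_rho, rng)
        dosages = hap1 + hap2
    else:
        dosages = rng.binomial(2, maf, size=(config.n_samples, config.n_snps))
    return GenotypeMatrix(
        dosages,
        [f"S{i:04d}" for i in range(config.n_samples)],
        [f"snp{j:05d}" for j in range(config.n_snps)],
        ["1"] * config.n_snps,
        positions,
        empirical_maf(dosages),
    )


def _markov_haplotypes(maf, n, rho, rng):
    """First-order Markov chain along SNPs: copy the neighbouring allele
    with probability rho, else draw fresh at that SNP's frequency."""
    m = maf.size
    hap = np.empty((n, m), dtype=np.int8)
    hap[:, 0] = rng.random(n) < maf[0]
    for j in range(1, m):
        copy = rng.random(n) < rho
        fresh = rng.random(n) < maf[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def simulate_eqtl_dataset(
    G: GenotypeMatrix | None = None, config: EQTLSimConfig | None = None, **overrides
) -> SimulatedEQTLDataset:
    """Layer multi-tissue expression with known cis architecture on top of a
    genotype matrix (generated from the config when not supplied)."""
    if config is None:
        config = EQTLSimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    if G is None:
        G = simulate_genotypes(config)
    if G.n_samples != config.n_samples:
        raise ValueError(
            f"genotype matrix has {G.n_samples} samples, config says {config.n_samples}"
        )
    rng = np.random.default_rng(config.seed + 101)
    n, m = G.n_samples, G.n_snps
    g = config.n_genes
    tissues = [f"T{t+1}" for t in range(config.n_tissues)]
    gene_ids = [f"G{j:04d}" for j in range(g)]
    tss = np.sort(rng.integers(1, config.region_length + 1, size=g))

    # cis SNP index per gene
    lo = np.searchsorted(G.positions, tss - config.window_bp, side="left")
    hi = np.searchsorted(G.positions, tss + config.window_bp, side="right")
    for j in range(g):
        if hi[j] - lo[j] < config.causal_range[1]:
            raise ValueError(
                f"gene {gene_ids[j]} has only {hi[j]-lo[j]} SNPs within "
                f"{config.window_bp} bp of its TSS"
            )

    # sharing structure
    n_egenes = int(round(config.frac_egenes * g))
    egene_idx = rng.choice(g, size=n_egenes, replace=False)
    p_shared, p_spec, p_uniq = config.sharing_proportions
    n_shared = int(round(p_shared * n_egenes))
    n_spec = int(round(p_spec * n_egenes))
    cats = (["shared"] * n_shared + ["tissue_specific"] * n_spec
            + ["unique"] * (n_egenes - n_shared - n_spec))
    sharing = {gid: "none" for gid in gene_ids}
    for j, cat in zip(egene_idx, cats):
        sharing[gene_ids[j]] = cat

    # covariates shared by every tissue (same individuals)
    batch = rng.integers(0, 3, size=n)
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(20.0, 80.0, size=n)
    age_std = (age - 50.0) / 30.0
    sex_sign = 2.0 * sex - 1.0
    conf_design = np.column_stack(
        [
            np.eye(3)[batch],
            sex_sign,
            age_std,
            age_std**2 - np.mean(age_std**2),
            np.eye(3)[batch] * sex_sign[:, None],
        ]
    )

    dos = G.dosages.astype(np.float64)
    poly = G.maf > 0  # monomorphic SNPs carry no signal and break MAF scaling
    snp_scale = np.zeros(m)
    snp_scale[poly] = (2.0 * G.maf[poly] * (1.0 - G.maf[poly])) ** -0.5  # alpha=1

    def draw_causal(j: int) -> list:
        k = int(rng.integers(config.causal_range[0], config.causal_range[1] + 1))
        pool = np.arange(lo[j], hi[j])
        pool = pool[poly[pool]]
        if pool.size < k:
            raise ValueError(
                f"gene {gene_ids[j]} has only {pool.size} polymorphic SNPs in cis"
            )
        snps = rng.choice(pool, size=k, replace=False)
        betas = rng.standard_normal(k) * snp_scale[snps]
        return [(int(s), float(b)) for s, b in zip(snps, betas)]

    causal_sets: dict = {}
    h2: dict = {}
    egene_truth: dict = {}
    expression: dict = {}
    genetic_values: dict = {}

    # decide per-gene causal architecture
    per_gene_tissue_sets: dict = {}
    for j, gid in enumerate(gene_ids):
        cat = sharing[gid]
        if cat == "none":
            continue
        if cat == "shared":
            one = draw_causal(j)
            per_gene_tissue_sets[gid] = {t: one for t in tissues}
        elif cat == "tissue_specific":
            per_gene_tissue_sets[gid] = {t: draw_causal(j) for t in tissues}
        else:  # unique: a single random tissue
            t = tissues[int(rng.integers(config.n_tissues))]
            per_gene_tissue_sets[gid] = {t: draw_causal(j)}

    vc = config.confounder_var
    for t_idx, tissue in enumerate(tissues):
        expr = np.empty((n, g))
        gvals = np.zeros((n, g))
        affected = np.zeros(g, bool)
        affected[rng.choice(g, size=int(round(config.frac_affected * g)), replace=False)] = True
        conf_coefs = rng.standard_normal((conf_design.shape[1], g)) * affected[None, :]
        conf_raw = conf_design @ conf_coefs
        sd = conf_raw.std(axis=0)
        sd[sd == 0] = 1.0
        conf_signal = conf_raw / sd * np.sqrt(vc) * affected[None, :]
        for j, gid in enumerate(gene_ids):
            tset = per_gene_tissue_sets.get(gid, {})
            causal = tset.get(tissue, [])
            is_egene = bool(causal)
            egene_truth[(gid, tissue)] = is_egene
            var_c = vc if affected[j] else 0.0
            if is_egene:
                target_h2 = float(rng.choice(config.h2_grid))
                if target_h2 + var_c >= 1.0:
                    raise ValueError(
                        f"h2 {target_h2} + confounder variance {var_c} >= 1 for {gid}"
                    )
                snps = np.array([s for s, _ in causal])
                betas = np.array([b for _, b in causal])
                gval = dos[:, snps] @ betas
                gstd = (gval - gval.mean()) / gval.std()
                gvals[:, j] = gstd
                h2[(gid, tissue)] = target_h2
                causal_sets[(gid, tissue)] = [
                    (G.snp_ids[s], float(b)) for s, b in causal
                ]
            else:
                target_h2 = 0.0
                gstd = 0.0
            resid_sd = np.sqrt(max(1.0 - target_h2 - var_c, 0.0)) * config.noise_scale[t_idx]
            expr[:, j] = (
                np.sqrt(target_h2) * gstd
                + conf_signal[:, j]
                + rng.normal(0.0, resid_sd, size=n)
            )
        expression[tissue] = ExpressionMatrix(expr, list(G.sample_ids), gene_ids, "log2")
        genetic_values[tissue] = gvals

    cov = CovariateTable(
        list(G.sample_ids),
        pd.DataFrame({"batch": batch, "sex": sex, "age": age}),
        {"batch": "categorical", "sex": "categorical", "age": "continuous"},
    )
    return SimulatedEQTLDataset(
        genotypes=G,
        expression=expression,
        gene_positions=tss,
        gene_ids=gene_ids,
        causal_sets=causal_sets,
        h2=h2,
        egene_truth=egene_truth,
        covariates=cov,
        tissue_sharing=sharing,
        genetic_values=genetic_values,
        config=config,
    )
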