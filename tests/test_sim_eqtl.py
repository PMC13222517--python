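import numpy as np
import pytest

from usadae.sim_eqtl import EQTLSimConfig, simulate_eqtl_dataset, simulate_genotypes


@pytest.fixture(scope="module")
def small_config():
    return EQTLSimConfig(
        n_genes=60, n_tissues=3, n_snps=800, n_samples=200,
        region_length=4_000_000, seed=3,
    )


@pytest.fixture(scope="module")
def small_dataset(small_config):
    return simulate_eqtl_dataset(config=small_config)


class TestGenotypes:
    def test_dosages_in_range_and_positions_sorted(self, small_config):
        g = simulate_genotypes(small_config)
        assert np.isin(g.dosages, (0, 1, 2)).all()
        assert (np.diff(g.positions) > 0).all()

    def test_default_snp_count(self):
        g = simulate_genotypes(EQTLSimConfig(n_samples=20, seed=0))
        assert g.n_snps == 10_000

    def test_empirical_maf_near_drawn_maf(self):
        cfg = EQTLSimConfig(n_genes=10, n_snps=500, n_samples=500, seed=9)
        rng = np.random.default_rng(cfg.seed)
        drawn = rng.uniform(cfg.maf_min, 0.5, size=cfg.n_snps)
        g = simulate_genotypes(cfg)
        p_hat = g.dosages.mean(axis=0) / 2
        p_hat = np.minimum(p_hat, 1 - p_hat)
        bound = 4 * np.sqrt(drawn * (1 - drawn) / (2 * cfg.n_samples))
        assert (np.abs(p_hat - np.minimum(drawn, 1 - drawn)) <= bound).mean() > 0.99

    def test_markov_ld_mode_induces_neighbor_correlation(self):
        cfg = EQTLSimConfig(n_genes=10, n_snps=300, n_samples=400, ld_rho=0.8, seed=2)
        g = simulate_genotypes(cfg)
        r = [
            np.corrcoef(g.dosages[:, j], g.dosages[:, j + 1])[0, 1]
            for j in range(0, 250, 7)
        ]
        assert np.nanmean(r) > 0.3


class TestEQTLDataset:
    def test_dimensions_and_tissues(self, small_dataset, small_config):
        assert len(small_dataset.expression) == 3
        for mat in small_dataset.expression.values():
            assert mat.values.shape == (small_config.n_samples, small_config.n_genes)

    def test_default_scale_contract(self):
        ds = simulate_eqtl_dataset(config=EQTLSimConfig(n_samples=30, seed=1))
        assert ds.config.n_genes == 2000 and ds.config.n_tissues == 3
        assert ds.genotypes.n_snps == 10_000

    def test_causal_sets_within_window_and_size_range(self, small_dataset, small_config):
        pos = {s: p for s, p in zip(small_dataset.genotypes.snp_ids,
                                    small_dataset.genotypes.positions)}
        tss = dict(zip(small_dataset.gene_ids, small_dataset.gene_positions))
        for (gene, tissue), causal in small_dataset.causal_sets.items():
            assert 5 <= len(causal) <= 15
            for snp, _beta in causal:
                assert abs(pos[snp] - tss[gene]) <= small_config.window_bp

    def test_h2_within_stated_range(self, small_dataset):
        for h2 in small_dataset.h2.values():
            assert 0.005 <= h2 <= 0.80

    def test_realized_h2_tracks_target(self):
        cfg = EQTLSimConfig(
            n_genes=40, n_tissues=1, n_snps=600, n_samples=500,
            region_length=3_000_000, confounder_var=0.0, frac_affected=0.0,
            noise_scale=(1.0,), seed=5,
        )
        ds = simulate_eqtl_dataset(config=cfg)
        tissue = ds.tissues[0]
        expr = ds.expression[tissue].values
        gvals = ds.genetic_values[tissue]
        for j, gid in enumerate(ds.gene_ids):
            if not ds.egene_truth[(gid, tissue)]:
                continue
            r2 = np.corrcoef(expr[:, j], gvals[:, j])[0, 1] ** 2
            assert abs(r2 - ds.h2[(gid, tissue)]) < 0.05

    def test_non_egenes_uncorrelated_with_cis_snps(self, small_dataset):
        g = small_dataset.genotypes
        tissue = small_dataset.tissues[0]
        expr = small_dataset.expression[tissue].values
        n = g.n_samples
        rs = []
        for j, gid in enumerate(small_dataset.gene_ids):
            if small_dataset.egene_truth[(gid, tissue)]:
                continue
            tss = small_dataset.gene_positions[j]
            cis = np.flatnonzero(np.abs(g.positions - tss) <= 1_000_000)[:20]
            for s in cis:
                rs.append(np.corrcoef(expr[:, j], g.dosages[:, s])[0, 1])
        # mean |r| of null correlations ~ sqrt(2/(pi n)); allow 3 SE
        expected = np.sqrt(2 / (np.pi * n))
        se = expected / np.sqrt(len(rs))
        assert abs(np.mean(np.abs(rs)) - expected) < 5 * se

    def test_sharing_counts_conserved(self, small_dataset, small_config):
        counts = {"shared": 0, "tissue_specific": 0, "unique": 0, "none": 0}
        for cat in small_dataset.tissue_sharing.values():
            counts[cat] += 1
        n_egenes = round(small_config.frac_egenes * small_config.n_genes)
        p_sh, p_sp, p_un = small_config.sharing_proportions
        assert abs(counts["shared"] - p_sh * n_egenes) <= 1
        assert abs(counts["tissue_specific"] - p_sp * n_egenes) <= 1
        assert abs(counts["unique"] - p_un * n_egenes) <= 1

    def test_sharing_semantics(self, small_dataset):
        tissues = small_dataset.tissues
        for gid, cat in small_dataset.tissue_sharing.items():
            sets = [
                frozenset(s for s, _ in small_dataset.causal_sets.get((gid, t), []))
                for t in tissues
            ]
            if cat == "shared":
                assert all(s == sets[0] and s for s in sets)
            elif cat == "unique":
                assert sum(bool(s) for s in sets) == 1
            elif cat == "none":
                assert not any(sets)

    def test_gene_without_cis_snps_is_an_error(self):
        cfg = EQTLSimConfig(
            n_genes=30, n_snps=10, n_samples=20,
            region_length=500_000_000, seed=0,
        )
        with pytest.raises(ValueError, match="G"):
            simulate_eqtl_dataset(config=cfg)

    def test_stacked_expression_labels(self, small_dataset, small_config):
        stacked, labels = small_dataset.stacked_expression()
        assert stacked.values.shape == (
            small_config.n_samples * 3, small_config.n_genes
        )
        assert set(labels) == {0, 1, 2}

    def test_writer_outputs(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        for f in ("dosages.tsv", "snp_map.tsv", "covariates.tsv",
                  "gene_positions.tsv", "truth.tsv", "manifest.json",
                  "expression_T1.tsv"):
            assert (tmp_path / f).exists(), f
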