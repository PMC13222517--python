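import numpy as np
import pandas as pd
import pytest
from scipy import stats

from usadae.data_io import ExpressionMatrix, GenotypeMatrix, empirical_maf
from usadae.downstream import (
    DEAResult,
    bh_adjust,
    call_degs,
    dea_linear,
    map_cis_eqtl,
)


class TestBH:
    def test_reproduces_hand_worked_step_up(self):
        # classic 10-p example worked by hand with the step-up rule
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.2, 0.3, 0.4, 0.5, 0.6])
        # q_i = min_{j >= i} p_j * 10 / j
        by_hand = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 1 / 3, 3 / 7, 0.5, 5 / 9, 0.6])
        np.testing.assert_allclose(bh_adjust(p), by_hand, rtol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDEALinear:
    def test_symmetric_null_gene(self):
        x = np.array([[1.0], [1.0], [2.0], [2.0]])
        group = np.array([0, 1, 0, 1])
        res = dea_linear(x, group)
        assert res.log2fc[0] == pytest.approx(0.0)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_equals_two_sample_t_test(self):
        # 6 hand-listed values; OLS on [1, group] reproduces the pooled-variance t test
        y = np.array([3.1, 2.9, 3.4, 4.0, 4.3, 4.1])
        group = np.array([0, 0, 0, 1, 1, 1])
        res = dea_linear(y[:, None], group)
        t_ref, p_ref = stats.ttest_ind(y[group == 1], y[group == 0], equal_var=True)
        assert res.t_stat[0] == pytest.approx(t_ref)
        assert res.p_value[0] == pytest.approx(p_ref)
        assert res.log2fc[0] == pytest.approx(y[3:].mean() - y[:3].mean())

    def test_null_p_values_uniform_across_seeds(self):
        # KS statistic below the 5% critical value in >= 90% of 20 seeds
        n, g = 60, 300
        crit = 1.358 / np.sqrt(g)  # asymptotic 5% KS critical value
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(n, g))
            group = np.repeat([0, 1], n // 2)
            res = dea_linear(x, group)
            d = stats.kstest(res.p_value, "uniform").statistic
            ok += d < crit
        assert ok >= 18

    def test_covariate_adjustment_changes_estimates(self, rng):
        n = 80
        group = np.repeat([0, 1], n // 2)
        conf = rng.normal(size=n) + 0.8 * group
        x = (2.0 * conf + rng.normal(0, 0.3, size=n))[:, None]
        res_no = dea_linear(x, group)
        res_adj = dea_linear(x, group, conf[:, None])
        assert abs(res_adj.log2fc[0]) < abs(res_no.log2fc[0])

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=(20, 3))
        group = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="collinear"):
            dea_linear(x, group, group[:, None].astype(float))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            dea_linear(rng.normal(size=(3, 2)), np.array([0, 1, 0]), rng.normal(size=(3, 2)))


class TestCallDegs:
    def _res(self, p_adj, fc):
        n = len(p_adj)
        return DEAResult(
            [f"g{i}" for i in range(n)],
            np.asarray(fc, float),
            np.zeros(n),
            np.asarray(p_adj, float),
            np.asarray(p_adj, float),
        )

    def test_boundaries_are_strict(self):
        res = self._res([0.05, 0.049], [1.0, 0.263])
        np.testing.assert_array_equal(call_degs(res), [False, False])

    def test_toy_table_enumeration(self):
        res = self._res(
            [0.01, 0.049, 0.051, 0.2, 0.001],
            [0.5, -0.3, 0.9, 0.264, 0.1],
        )
        np.testing.assert_array_equal(
            call_degs(res), [True, True, False, False, False]
        )


def _toy_genotypes(rng, n=50, m=3, positions=(1000, 5000, 2_100_000)):
    dos = rng.integers(0, 3, size=(n, m))
    return GenotypeMatrix(
        dos,
        [f"s{i}" for i in range(n)],
        [f"snp{j}" for j in range(m)],
        ["1"] * m,
        np.asarray(positions),
        empirical_maf(dos),
    )


class TestCisEQTL:
    def test_window_is_inclusive(self, rng):
        g = _toy_genotypes(rng, positions=(1000, 1_001_000, 1_001_001))
        expr = ExpressionMatrix(
            rng.normal(size=(50, 1)), g.sample_ids, ["gene"], "log2"
        )
        res = map_cis_eqtl(g, expr, [1000], window_bp=1_000_000)
        tested = set(res.pairs["snp_id"])
        assert "snp1" in tested  # distance exactly 1 Mb: inclusive
        assert "snp2" not in tested  # 1 Mb + 1: excluded

    def test_perfect_association(self, rng):
        g = _toy_genotypes(rng)
        expr = ExpressionMatrix(
            g.dosages[:, 0:1].astype(float), g.sample_ids, ["gene"], "log2"
        )
        res = map_cis_eqtl(g, expr, [1000])
        row = res.pairs[res.pairs.snp_id == "snp0"].iloc[0]
        assert row.slope == pytest.approx(1.0, abs=1e-10)
        assert row.p_nominal < 1e-100

    def test_residualization_matches_full_design_ols(self, rng):
        # Frisch-Waugh: per-pair slope/SE from residualized regression equal
        # the genotype coefficient of the joint OLS with the covariate
        import statsmodels.api as sm

        g = _toy_genotypes(rng, positions=(1000, 2000, 3000))
        cov = rng.normal(size=(50, 1))
        y = rng.normal(size=50)
        expr = ExpressionMatrix(y[:, None], g.sample_ids, ["gene"], "log2")
        res = map_cis_eqtl(g, expr, [1500], covariates=cov)
        for j in range(3):
            X = sm.add_constant(
                np.column_stack([cov, g.dosages[:, j].astype(float)])
            )
            fit = sm.OLS(y, X).fit()
            row = res.pairs[res.pairs.snp_id == f"snp{j}"].iloc[0]
            assert row.slope == pytest.approx(fit.params[-1], rel=1e-9)
            assert row.se == pytest.approx(fit.bse[-1], rel=1e-9)
            assert row.p_nominal == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_gene_without_cis_snps_is_untestable(self, rng):
        g = _toy_genotypes(rng, positions=(1000, 2000, 3000))
        expr = ExpressionMatrix(
            rng.normal(size=(50, 1)), g.sample_ids, ["far_gene"], "log2"
        )
        res = map_cis_eqtl(g, expr, [50_000_000])
        assert res.untestable == ["far_gene"]
        assert len(res.genes) == 0

    def test_monomorphic_snp_skipped(self, rng):
        g = _toy_genotypes(rng)
        g.dosages[:, 1] = 1  # monomorphic
        expr = ExpressionMatrix(
            rng.normal(size=(50, 1)), g.sample_ids, ["gene"], "log2"
        )
        res = map_cis_eqtl(g, expr, [1500])
        assert "snp1" not in set(res.pairs["snp_id"])

    def test_bonferroni_gene_p(self, rng):
        g = _toy_genotypes(rng, positions=(1000, 2000, 3000))
        expr = ExpressionMatrix(
            rng.normal(size=(50, 1)), g.sample_ids, ["gene"], "log2"
        )
        res = map_cis_eqtl(g, expr, [1500])
        gene = res.genes.iloc[0]
        assert gene.p_gene == pytest.approx(min(gene.p_min * gene.n_cis, 1.0))
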