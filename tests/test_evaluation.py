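import numpy as np
import pandas as pd
import pytest
from scipy import stats

from usadae.downstream import DEAResult, EQTLResult
from usadae.evaluation import (
    evaluate_covariate_prediction,
    evaluate_dea,
    evaluate_egene_detection,
    latent_independence_score,
    replication_rate,
)


class TestCovariatePrediction:
    def test_leaked_target_gives_perfect_auc(self, rng):
        y = rng.integers(0, 2, size=100)
        Z = np.column_stack([y.astype(float), rng.normal(size=100)])
        rec = evaluate_covariate_prediction(Z, y, "classification", "logistic", seed=0)
        assert all(a == 1.0 for a in rec.fold_scores["auc"])

    def test_permuted_labels_give_chance_auc(self, rng):
        Z = rng.normal(size=(200, 5))
        aucs = []
        for seed in range(10):
            y = np.random.default_rng(seed).integers(0, 2, size=200)
            rec = evaluate_covariate_prediction(Z, y, "classification", "logistic", seed=seed)
            aucs.append(rec.mean("auc"))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_exact_linear_target_gives_unit_r2(self, rng):
        Z = rng.normal(size=(100, 4))
        y = Z @ np.array([1.0, -2.0, 0.5, 3.0]) + 7.0
        rec = evaluate_covariate_prediction(Z, y, "regression", "linear", seed=0)
        assert rec.mean("r2") == pytest.approx(1.0, abs=1e-6)

    def test_sample_order_invariance(self, rng):
        Z = rng.normal(size=(80, 3))
        y = (Z[:, 0] > 0).astype(int)
        rec1 = evaluate_covariate_prediction(Z, y, "classification", "logistic", seed=3)
        perm = rng.permutation(80)
        rec2 = evaluate_covariate_prediction(Z[perm], y[perm], "classification", "logistic", seed=3)
        assert rec1.mean("auc") == pytest.approx(rec2.mean("auc"), abs=0.05)

    def test_rare_class_suggests_fewer_folds(self, rng):
        Z = rng.normal(size=(20, 2))
        y = np.zeros(20, int)
        y[:3] = 1
        with pytest.raises(ValueError, match="folds"):
            evaluate_covariate_prediction(Z, y, "classification", folds=5)

    def test_multiclass_macro_metrics_present(self, rng):
        Z = rng.normal(size=(90, 4))
        y = rng.integers(0, 3, size=90)
        rec = evaluate_covariate_prediction(Z, y, "classification", "random_forest", seed=1)
        assert set(rec.fold_scores) == {"auc", "f1", "precision", "recall"}
        assert len(rec.fold_scores["auc"]) == 5


class TestEvaluateDEA:
    def _res(self, p):
        n = len(p)
        return DEAResult([f"g{i}" for i in range(n)], np.ones(n), np.ones(n),
                         np.asarray(p, float), np.asarray(p, float))

    def test_perfect_ordering_gives_unit_auc(self):
        truth = np.array([True, True, False, False])
        res = self._res([0.001, 0.002, 0.5, 0.9])
        assert evaluate_dea(res, truth)["auc"] == 1.0

    def test_random_p_values_give_half_auc(self, rng):
        truth = np.arange(2000) < 1000
        res = self._res(rng.uniform(size=2000))
        assert evaluate_dea(res, truth)["auc"] == pytest.approx(0.5, abs=0.05)

    def test_matches_mann_whitney(self, rng):
        truth = np.array([True, False, True, False, True, False])
        p = np.array([0.01, 0.4, 0.03, 0.2, 0.6, 0.05])
        auc = evaluate_dea(self._res(p), truth)["auc"]
        u = stats.mannwhitneyu(-p[truth], -p[~truth], alternative="greater").statistic
        assert auc == pytest.approx(u / (3 * 3))

    def test_degenerate_truth_warns_and_drops_auc(self):
        res = self._res([0.1, 0.2])
        with pytest.warns(UserWarning):
            out = evaluate_dea(res, np.array([True, True]))
        assert out["auc"] is None


class TestEGeneDetection:
    def _result(self, flags):
        genes = pd.DataFrame(
            {"gene_id": list(flags), "n_cis": 1, "best_snp": "s", "p_min": 0.01,
             "p_gene": 0.01, "p_adj": 0.01, "egene": list(flags.values())}
        )
        return EQTLResult(pd.DataFrame(), genes, [])

    def test_perfect_calls(self):
        truth = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "egene": [1, 1, 0, 0],
             "h2": [0.1, 0.5, 0.0, 0.0]}
        )
        res = self._result({"a": True, "b": True, "c": False, "d": False})
        out = evaluate_egene_detection(res, truth, [0.0, 0.3, 1.0])
        assert (out.dropna()["precision"] == 1.0).all()
        assert (out.dropna()["recall"] == 1.0).all()

    def test_no_calls_gives_zero_recall_missing_precision(self):
        truth = pd.DataFrame(
            {"gene_id": ["a", "b"], "egene": [1, 1], "h2": [0.1, 0.1]}
        )
        res = self._result({"a": False, "b": False})
        out = evaluate_egene_detection(res, truth, [0.0, 1.0])
        assert out["recall"].iloc[0] == 0.0
        assert np.isnan(out["precision"].iloc[0])

    def test_toy_counts(self):
        truth = pd.DataFrame(
            {"gene_id": list("abcdefgh"), "egene": [1, 1, 1, 0, 0, 0, 1, 0],
             "h2": [0.1] * 8}
        )
        flags = dict(zip("abcdefgh", [True, False, True, True, False, False, False, False]))
        out = evaluate_egene_detection(self._result(flags), truth, [0.0, 1.0])
        assert out["precision"].iloc[0] == pytest.approx(2 / 3)
        assert out["recall"].iloc[0] == pytest.approx(2 / 4)


class TestReplicationRate:
    def test_identical_sets_give_unit_pi(self):
        sets = [{("g", "s1"), ("g", "s2")}] * 5
        res = replication_rate(sets)
        for k in range(1, 5):
            assert (res.per_fold[f"pi_{k}"] == 1.0).all()

    def test_disjoint_sets_give_zero_pi(self):
        sets = [{(f"g{i}", "s")} for i in range(5)]
        res = replication_rate(sets)
        for k in range(1, 5):
            assert (res.per_fold[f"pi_{k}"] == 0.0).all()

    def test_printed_formula_on_toy_sets(self):
        # discovery fold 0 has 10 signals; 3 of them occur in >= 2 other folds
        discovery = {f"sig{i}" for i in range(10)}
        rep1 = {"sig0", "sig1", "sig2", "sig5"}
        rep2 = {"sig0", "sig1", "sig2"}
        rep3, rep4 = {"sig9"}, set()
        res = replication_rate([discovery, rep1, rep2, rep3, rep4])
        row = res.per_fold.iloc[0]
        assert row["pi_2"] == pytest.approx(0.3)
        assert row["N"] == 10

    def test_monotone_in_k(self, rng):
        sets = [
            set(rng.choice(50, size=rng.integers(5, 20), replace=False).tolist())
            for _ in range(5)
        ]
        res = replication_rate(sets)
        pis = res.per_fold[[f"pi_{k}" for k in range(1, 5)]].to_numpy()
        assert (np.diff(pis, axis=1) <= 1e-12).all()

    def test_empty_discovery_reported_missing(self):
        with pytest.warns(UserWarning, match="empty"):
            res = replication_rate([set(), {"a"}, {"a"}, {"b"}, set()])
        assert np.isnan(res.per_fold.iloc[0]["pi_1"])


class TestLatentIndependence:
    def test_copied_latents_detected(self, rng):
        Z = rng.normal(size=(100, 5))
        stat, p = latent_independence_score(Z, Z.copy(), n_perm=99, seed=0)
        assert stat > 0.99
        assert p == pytest.approx(1 / 100)

    def test_independent_latents_not_detected(self, rng):
        ps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            stat, p = latent_independence_score(
                r.normal(size=(500, 4)), r.normal(size=(500, 4)), n_perm=99, seed=seed
            )
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.3

    def test_single_shared_column(self, rng):
        shared = rng.normal(size=100)
        Zb = np.column_stack([shared, rng.normal(size=(100, 3))])
        Zc = np.column_stack([shared, rng.normal(size=(100, 3))])
        stat, p = latent_independence_score(Zb, Zc, n_perm=99, seed=1)
        assert stat > 0.99

    def test_constant_column_dropped_with_warning(self, rng):
        Zb = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        with pytest.warns(UserWarning, match="constant"):
            latent_independence_score(Zb, rng.normal(size=(50, 3)), n_perm=19, seed=0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            latent_independence_score(
                rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
            )
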