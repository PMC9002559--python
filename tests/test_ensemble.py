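import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import invasipath as ip
from invasipath.ensemble import normalize_contributions


def pair_concordance_auc(y, s):
    """O(n^2) oracle: concordant pairs + half ties over all pos/neg pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def exhaustive_max_tss(y, s):
    best_tss, best_thr = -np.inf, None
    for t in np.unique(s):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        tss = sens + spec - 1
        # ties -> lowest threshold
        if tss > best_tss + 1e-12:
            best_tss, best_thr = tss, t
        elif abs(tss - best_tss) <= 1e-12 and t < best_thr:
            best_thr = t
    return best_thr


def toy_separable_table(n=40, rng=None):
    rng = rng or np.random.default_rng(0)
    x_pos = rng.uniform(1, 2, size=n)
    x_neg = rng.uniform(-2, -1, size=n)
    x2 = rng.normal(size=2 * n)
    X = pd.DataFrame({"x": np.concatenate([x_pos, x_neg]), "z": x2})
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    cells = np.zeros((2 * n, 2), dtype=int)
    return ip.TrainingTable(X=X, y=y, cells=cells,
                            kinds={"x": "continuous", "z": "continuous"})


class TestMetrics:
    @settings(derandomize=True, max_examples=100)
    @given(
        sens=st.floats(min_value=0.0, max_value=1.0),
        spec=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_identities_hold_for_any_rates(self, sens, spec):
        m = ip.EvaluationMetrics.from_rates(sens, spec)
        assert m.tss == pytest.approx(sens + spec - 1, abs=1e-12)
        assert m.omission_rate == pytest.approx(1 - sens, abs=1e-12)
        assert -1.0 - 1e-12 <= m.tss <= 1.0 + 1e-12

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.3, 0.1])
        m = ip.evaluate_scores(y, s)
        assert m.auc == pytest.approx(1.0)
        assert m.tss == pytest.approx(1.0)
        assert m.omission_rate == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        y = np.concatenate([np.ones(n // 2, int), np.zeros(n - n // 2, int)])
        s = np.round(rng.uniform(size=n), 1)  # coarse scores force ties
        m = ip.evaluate_scores(y, s)
        assert m.auc == pytest.approx(pair_concordance_auc(y, s), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_max_tss_threshold_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 40))
        y = (rng.uniform(size=n) < 0.4).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.uniform(size=n), 1)
        assert ip.max_tss_threshold(y, s) == pytest.approx(
            exhaustive_max_tss(y, s)
        )

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ip.evaluate_scores(np.ones(5, int), np.random.rand(5))


class TestSplit:
    def _table(self, n_pres, n_abs=100):
        X = pd.DataFrame({"x": np.arange(n_pres + n_abs, dtype=float)})
        y = np.concatenate([np.ones(n_pres, int), np.zeros(n_abs, int)])
        return ip.TrainingTable(X=X, y=y,
                                cells=np.zeros((n_pres + n_abs, 2), int),
                                kinds={"x": "continuous"})

    @pytest.mark.parametrize("n_pres,expect_train,expect_test",
                             [(40, 30, 10), (59, 44, 15)])
    def test_presence_split_counts(self, n_pres, expect_train, expect_test):
        train, test = ip.split_train_test(self._table(n_pres), seed=0)
        assert (train.y == 1).sum() == expect_train
        assert (test.y == 1).sum() == expect_test

    def test_stratification_within_one_row(self):
        table = self._table(41, 103)
        train, _ = ip.split_train_test(table, 0.75, seed=1)
        for label, n in ((1, 41), (0, 103)):
            got = (train.y == label).sum()
            assert abs(got - 0.75 * n) <= 1

    def test_rows_partition_disjointly(self):
        table = self._table(20, 50)
        train, test = ip.split_train_test(table, seed=3)
        assert len(train) + len(test) == len(table)
        ids = np.concatenate([train.X["x"], test.X["x"]])
        assert len(np.unique(ids)) == len(table)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="4 presences"):
            ip.split_train_test(self._table(3), seed=0)


class TestAlgorithms:
    @pytest.mark.parametrize("algo", ip.ALGORITHMS)
    def test_separable_data_gives_training_auc_one(self, algo):
        table = toy_separable_table()
        est = ip.fit_algorithm(algo, table, random_state=0)
        m = ip.evaluate(est, table)
        assert m.auc == pytest.approx(1.0)

    def test_null_predictors_give_chance_auc(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        y = (rng.uniform(size=n) < 0.5).astype(int)
        table = ip.TrainingTable(X=X, y=y, cells=np.zeros((n, 2), int),
                                 kinds={"x": "continuous", "z": "continuous"})
        train, test = ip.split_train_test(table, seed=0)
        est = ip.fit_algorithm("GLM", train, random_state=0)
        m = ip.evaluate(est, test)
        n1, n0 = (test.y == 1).sum(), (test.y == 0).sum()
        se = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))  # null AUC SE
        assert abs(m.auc - 0.5) < 3 * se

    def test_glm_recovers_logistic_coefficient(self):
        """beta known; our GLM estimate within 2 oracle SEs at n=2000."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n, beta = 2000, 1.5
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-beta * x))).astype(int)
        table = ip.TrainingTable(
            X=pd.DataFrame({"x": x}), y=y, cells=np.zeros((n, 2), int),
            kinds={"x": "continuous"},
        )
        est = ip.fit_algorithm("GLM", table, random_state=0)
        scaler = est.named_steps["pre"].named_transformers_["cont"]
        sd = np.sqrt(scaler.named_steps["scale"].var_[0])
        coef = est.named_steps["clf"].coef_[0][0] / sd
        oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(coef - beta) < 2 * oracle.bse[1] + abs(oracle.params[1] - beta)

    def test_single_class_training_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        table = ip.TrainingTable(X=X, y=np.ones(10, int),
                                 cells=np.zeros((10, 2), int),
                                 kinds={"x": "continuous"})
        with pytest.raises(ValueError, match="single class"):
            ip.fit_algorithm("GLM", table)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            ip.fit_algorithm("SVM", toy_separable_table())


class TestPseudoAbsences:
    def test_requested_count_unique_and_reproducible(self, small_bundle):
        stack = small_bundle["stack"]
        a = ip.generate_pseudo_absences(stack, n=500, seed=3)
        b = ip.generate_pseudo_absences(stack, n=500, seed=3)
        assert len(np.unique(a, axis=0)) == 500
        np.testing.assert_array_equal(a, b)

    def test_ten_thousand_on_large_raster(self):
        stack = ip.EnvStack(
            {"x": ip.RasterLayer(np.zeros((120, 120)), cell_size=100.0)}
        )
        cells = ip.generate_pseudo_absences(stack, n=10_000, seed=1)
        assert len(np.unique(cells, axis=0)) == 10_000

    def test_exhaustion_returns_all_cells(self):
        vals = np.full((3, 3), np.nan)
        vals[0, :3] = 1.0
        vals[1, :2] = 1.0
        stack = ip.EnvStack({"x": ip.RasterLayer(vals, cell_size=100.0)})
        cells = ip.generate_pseudo_absences(stack, n=5, seed=0)
        assert len(cells) == 5

    def test_overdraw_and_exclusion(self, small_bundle):
        stack = small_bundle["stack"]
        n_valid = int(stack.valid_mask.sum())
        with pytest.raises(ValueError, match="eligible"):
            ip.generate_pseudo_absences(stack, n=n_valid + 1)
        pres = small_bundle["occurrences"].cells(stack.grid, dedupe=True)
        cells = ip.generate_pseudo_absences(
            stack, n=n_valid - len(pres), seed=0, exclude=pres
        )
        pres_set = {tuple(c) for c in pres}
        assert not pres_set & {tuple(c) for c in cells}


@pytest.fixture(scope="module")
def fitted_ensemble(small_table):
    ens = ip.EnsembleSDM(
        algorithms=("MAXENT", "GLM", "RF"),
        n_replicates=2,
        auc_gate=0.0,  # retain everything: tests the combination rule
        categorical_features=[
            n for n, k in small_table.kinds.items() if k == "categorical"
        ],
        random_state=5,
    )
    ens._fit_table(small_table)
    return ens


class TestEnsembleCombination:
    def test_weights_normalized_and_proportional_to_auc(self, fitted_ensemble):
        w = fitted_ensemble.weights_
        assert sum(w.values()) == pytest.approx(1.0)
        aucs = {
            a: fitted_ensemble.algorithm_metrics_[a].auc for a in w
        }
        ratio = {a: w[a] / aucs[a] for a in w}
        vals = list(ratio.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_prediction_is_weighted_mean_of_algorithm_means(
        self, fitted_ensemble, small_table
    ):
        X = small_table.X.iloc[:50]
        expected = np.zeros(len(X))
        for algo, w in fitted_ensemble.weights_.items():
            recs = fitted_ensemble._per_algo[algo]
            p = np.mean(
                [r.estimator.predict_proba(X)[:, 1] for r in recs], axis=0
            )
            expected += w * p
        got = fitted_ensemble.predict_suitability(X)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got.min() >= 0.0 and got.max() <= 1.0

    def test_single_retained_model_is_identity(self, small_table):
        ens = ip.EnsembleSDM(
            algorithms=("GLM",), n_replicates=1, auc_gate=0.0,
            categorical_features=[
                n for n, k in small_table.kinds.items() if k == "categorical"
            ],
            random_state=1,
        )
        ens._fit_table(small_table)
        X = small_table.X.iloc[:30]
        single = ens._per_algo["GLM"][0].estimator.predict_proba(X)[:, 1]
        np.testing.assert_allclose(ens.predict_suitability(X), single,
                                   atol=1e-12)

    def test_uniform_weighting_averages_equally(self, small_table):
        ens = ip.EnsembleSDM(
            algorithms=("GLM", "MAXENT"), n_replicates=1, auc_gate=0.0,
            weighting="uniform",
            categorical_features=[
                n for n, k in small_table.kinds.items() if k == "categorical"
            ],
            random_state=1,
        )
        ens._fit_table(small_table)
        X = small_table.X.iloc[:30]
        p = np.mean(
            [
                ens._per_algo[a][0].estimator.predict_proba(X)[:, 1]
                for a in ("GLM", "MAXENT")
            ],
            axis=0,
        )
        np.testing.assert_allclose(ens.predict_suitability(X), p, atol=1e-12)

    def test_no_model_passes_gate_raises_with_aucs(self, small_table):
        ens = ip.EnsembleSDM(
            algorithms=("GLM",), n_replicates=1, auc_gate=0.9999,
            random_state=1,
        )
        with pytest.raises(RuntimeError, match="AUC gate"):
            ens._fit_table(small_table)

    def test_gate_is_strict_inequality(self, fitted_ensemble):
        # a model exactly at the gate must not be retained
        auc = fitted_ensemble.algorithm_metrics_["GLM"].auc
        ens = ip.EnsembleSDM(algorithms=("GLM",), auc_gate=auc)
        assert not auc > ens.auc_gate

    def test_sklearn_api(self, fitted_ensemble, small_table):
        X = small_table.X.iloc[:20]
        proba = fitted_ensemble.predict_proba(X)
        assert proba.shape == (20, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        pred = fitted_ensemble.predict(X)
        assert set(np.unique(pred)) <= {0, 1}
        params = fitted_ensemble.get_params()
        assert params["auc_gate"] == 0.0


class TestContributions:
    def test_normalization_matches_proportions(self):
        out = normalize_contributions({"a": 0.2, "b": 0.2, "c": 0.6})
        assert out == pytest.approx({"a": 20.0, "b": 20.0, "c": 60.0})
        assert sum(out.values()) == pytest.approx(100.0, abs=0.01)

    def test_uninformative_variable_contributes_zero(self, small_table):
        # a constant column: every refit without it predicts identically
        table = ip.TrainingTable(
            X=small_table.X.assign(const=1.0),
            y=small_table.y,
            cells=small_table.cells,
            kinds={**small_table.kinds, "const": "continuous"},
        )
        ens = ip.EnsembleSDM(
            algorithms=("GLM",), n_replicates=1, auc_gate=0.0,
            categorical_features=[
                n for n, k in table.kinds.items() if k == "categorical"
            ],
            random_state=2,
        )
        ens._fit_table(table)
        contrib = ip.variable_contributions(ens, table)
        assert contrib["const"] == pytest.approx(0.0, abs=1e-6)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.01)
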