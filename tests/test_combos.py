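"""Logistic marker combinations, pp thresholds, union strata."""

import numpy as np
import pandas as pd
import pytest

from admarker import combos, stratify
from admarker import endpoints as ep
from admarker.combos import UnionRule, enumerate_and_report, fit_combo_logistic, pp_threshold, union_stratify
from admarker.synth import PlantedMarker, TrialConfig, simulate_trial


def _frame(arrs):
    return pd.DataFrame({k: np.asarray(v, float) for k, v in arrs.items()})


class TestLogisticFit:
    def test_label_equal_predictor_separates(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        m = _frame({"A": y.astype(float)})
        model = fit_combo_logistic(m, y, ("A",))
        assert model.separation_detected
        pp = model.predict_pp(m)
        assert (pp[y] > pp[~y].max()).all()  # pp monotone in the predictor

    def test_coefficients_recovered_on_simulated_data(self):
        rng = np.random.default_rng(2)
        n = 500
        X = rng.normal(size=(n, 2))
        beta = np.array([-0.5, 1.0, -1.5])
        eta = beta[0] + X @ beta[1:]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        m = _frame({"A": X[:, 0], "B": X[:, 1]})
        model = fit_combo_logistic(m, y, ("A", "B"))
        assert model.converged and not model.separation_detected
        est = np.concatenate([[model.intercept], model.coefficients])
        assert np.all(np.abs(est - beta) <= 2 * model.standard_errors)

    def test_matches_sklearn_unpenalized(self):
        # independent optimizer as referee
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 2))
        y = rng.random(120) < 1 / (1 + np.exp(-(0.3 + X[:, 0] - 0.8 * X[:, 1])))
        m = _frame({"A": X[:, 0], "B": X[:, 1]})
        model = fit_combo_logistic(m, y, ("A", "B"))
        ref = LogisticRegression(penalty=None, tol=1e-10, max_iter=1000).fit(X, y)
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-5)
        assert np.allclose(model.coefficients, ref.coef_[0], atol=1e-5)

    def test_constant_column_rejected(self):
        y = np.array([0, 1, 0, 1, 0, 1], bool)
        m = _frame({"A": [1, 2, 3, 4, 5, 6], "B": [2, 2, 2, 2, 2, 2]})
        with pytest.raises(ValueError):
            fit_combo_logistic(m, y, ("A", "B"))

    def test_single_class_rejected(self):
        m = _frame({"A": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            fit_combo_logistic(m, np.ones(4, bool), ("A",))

    def test_log_transform_flag_changes_scale_not_ranking(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(size=60))
        y = rng.random(60) < 1 / (1 + np.exp(-(np.log(x) - 0.2)))
        m = _frame({"A": x})
        raw = fit_combo_logistic(m, y, ("A",), (False,))
        logged = fit_combo_logistic(m, y, ("A",), (True,))
        # both produce pp monotone in x when the slope is positive
        if logged.coefficients[0] > 0 and raw.coefficients[0] > 0:
            order = np.argsort(x)
            assert np.all(np.diff(logged.predict_pp(m)[order]) >= -1e-12)

    def test_affine_rescaling_leaves_pp_invariant(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(80, 2))
        y = rng.random(80) < 1 / (1 + np.exp(-(X[:, 0] - X[:, 1])))
        m1 = _frame({"A": X[:, 0], "B": X[:, 1]})
        m2 = _frame({"A": 100 * X[:, 0] + 7, "B": 0.01 * X[:, 1] - 3})
        p1 = fit_combo_logistic(m1, y, ("A", "B")).predict_pp(m1)
        p2 = fit_combo_logistic(m2, y, ("A", "B")).predict_pp(m2)
        assert np.allclose(p1, p2, atol=1e-6)


class TestPpThreshold:
    def test_pp_equal_to_labels_gives_midpoint_half(self):
        y = np.array([0, 0, 1, 1, 1, 0], bool)
        m = _frame({"A": y.astype(float)})
        model = fit_combo_logistic(m, y, ("A",))
        model = pp_threshold(model, m, y)
        assert model.auc_of_pp == 1.0
        pp = model.predict_pp(m)
        assert pp[~y].max() < model.pp_cutoff <= pp[y].min() + 1e-12

    def test_single_predictor_pp_ranking_matches_level_ranking(self, rng):
        x = rng.normal(size=30)
        y = rng.random(30) < 1 / (1 + np.exp(-2 * x))
        if y.all() or not y.any():
            y[:2] = [True, False]
        m = _frame({"A": x})
        model = fit_combo_logistic(m, y, ("A",))
        model = pp_threshold(model, m, y)
        sign = np.sign(model.coefficients[0])
        assert model.auc_of_pp == pytest.approx(
            max(stratify.auroc(sign * x, y), 1 - stratify.auroc(sign * x, y))
        )

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=200)
        y = rng.permutation([True] * 100 + [False] * 100)
        m = _frame({"A": x})
        model = pp_threshold(fit_combo_logistic(m, y, ("A",)), m, y)
        assert abs(model.auc_of_pp - 0.5) < 0.12

    def test_degenerate_equal_pp_has_no_threshold(self):
        y = np.array([0, 1, 0, 1], bool)
        m = _frame({"A": [1.0, 1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0, 4.0]})
        model = fit_combo_logistic(m, y, ("B",))
        model.coefficients = np.array([0.0])  # degenerate flat model
        model = pp_threshold(model, m, y)
        assert model.pp_cutoff is None


class TestUnionStratify:
    def _matrix(self):
        return pd.DataFrame(
            {"A": [1.0, 2, 3, 4, 5, 6], "B": [10.0, 20, 30, 40, 50, 60]},
            index=[f"p{i}" for i in range(6)],
        )

    def test_single_clause_reduces_to_marker_stratum(self):
        m = self._matrix()
        rule = UnionRule((("A", "hi", 3.5),))
        assert union_stratify(m, rule).tolist() == (m["A"] >= 3.5).tolist()

    def test_disjoint_clauses_union_sizes_add(self):
        m = self._matrix()
        rule = UnionRule((("A", "lo", 1.5), ("B", "hi", 55.0)))
        fav = union_stratify(m, rule)
        assert fav.sum() == 2  # p0 via A-lo, p5 via B-hi

    def test_covering_clauses_give_everyone(self):
        m = self._matrix()
        rule = UnionRule((("A", "hi", 0.0), ("B", "lo", 100.0)))
        assert union_stratify(m, rule).all()

    def test_monotone_in_clauses(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=["A", "B", "C"])
        base = UnionRule((("A", "hi", 0.0),))
        wider = UnionRule((("A", "hi", 0.0), ("B", "lo", 0.0)))
        assert (union_stratify(m, base) <= union_stratify(m, wider)).all()

    def test_label_formatting(self):
        rule = UnionRule((("K", "hi", 1.0), ("E", "lo", 2.0)))
        assert rule.label == "K^hi or E^lo"


class TestEnumerateAndReport:
    @pytest.fixture(scope="class")
    def planted_trial(self):
        cfg = TrialConfig(
            planted_markers=(
                PlantedMarker(1, "hi", 0.3, 2.5),
                PlantedMarker(4, "lo", 0.4, 2.5),
            ),
            responsive_fraction=0.3, n_proteins=8, seed=23,
        )
        trial = simulate_trial(cfg)
        endpoints = ep.compute_endpoints(trial.cohort)
        act = endpoints["arm"] == "high_dose"
        flags = endpoints.loc[act, "easi50_wk4"].astype(bool).to_numpy()
        mat_act = trial.proteome.loc[endpoints.loc[act, "patient_id"]]
        deps = stratify.select_deps(mat_act, flags, auroc_min=0.6)
        return trial, endpoints, deps

    def test_planted_pair_ranks_first_among_unions(self, planted_trial):
        trial, endpoints, deps = planted_trial
        report = enumerate_and_report(trial.proteome, deps, endpoints, k=2)
        unions = report[report["pathway"] == "union"]
        top = unions.iloc[0]["stratum"]
        assert "P0001^hi" in top or "P0004^lo" in top

    def test_k1_reduces_to_single_marker_report(self, planted_trial):
        trial, endpoints, deps = planted_trial
        report = enumerate_and_report(trial.proteome, deps, endpoints, k=1)
        unions = report[report["pathway"] == "union"]
        assert len(unions) == len(deps)
        single = {c.protein_id for c in deps}
        assert {s.split("^")[0] for s in unions["stratum"]} == single

    def test_budget_gate(self, planted_trial):
        trial, endpoints, deps = planted_trial
        if len(deps) < 3:
            pytest.skip("needs >= 3 screened markers")
        with pytest.raises(ValueError, match="budget"):
            enumerate_and_report(trial.proteome, deps, endpoints, k=2, max_combos=1)

    def test_deterministic_ordering(self, planted_trial):
        trial, endpoints, deps = planted_trial
        r1 = enumerate_and_report(trial.proteome, deps, endpoints, k=2)
        r2 = enumerate_and_report(trial.proteome, deps, endpoints, k=2)
        pd.testing.assert_frame_equal(r1, r2)
        orp = r1["or_p"].fillna(np.inf)
        assert (orp.diff().dropna() >= -1e-12).all()
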