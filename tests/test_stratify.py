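"""Single-marker engine: AUROC, Youden cut-offs, odds ratios, benefit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from admarker import endpoints as ep
from admarker import stratify
from admarker.stratify import (
    AssociationResult,
    ContingencyTable,
    CutoffResult,
    auroc,
    benefit_indicator,
    fisher_exact,
    odds_ratio_ha,
    select_deps,
    stratify_and_confusion,
    stratum_report,
    youden_optimal_cutoff,
)
from admarker.synth import PlantedMarker, TrialConfig, simulate_trial
from conftest import random_instance


@st.composite
def labelled_levels(draw):
    n = draw(st.integers(4, 25))
    ties = draw(st.booleans())
    if ties:
        x = draw(st.lists(st.integers(0, 4), min_size=n, max_size=n))
    else:
        x = draw(st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n))
    y = draw(
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda v: any(v) and not all(v)
        )
    )
    return np.asarray(x, float), np.asarray(y, bool)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=100, derandomize=True)
    @given(labelled_levels())
    def test_equals_exhaustive_pair_counting(self, instance):
        x, y = instance
        assert auroc(x, y) == pytest.approx(oracles.pairwise_auroc(x, y), abs=1e-12)

    def test_matrix_variant_agrees_with_scalar(self, rng):
        m = pd.DataFrame(rng.normal(size=(25, 8)), columns=[f"P{i}" for i in range(8)])
        y = rng.random(25) < 0.4
        y[0], y[1] = True, False
        per = stratify.auroc_matrix(m, y)
        for c in m.columns:
            assert per[c] == pytest.approx(auroc(m[c], y))


class TestYouden:
    def test_perfectly_separated_hi(self):
        r = youden_optimal_cutoff([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.j == 1.0 and r.direction == "hi"
        assert 3 < r.cutoff < 10
        assert r.j == pytest.approx(r.sensitivity + r.specificity - 1)

    @settings(max_examples=100, derandomize=True)
    @given(labelled_levels())
    def test_dominates_brute_force_scan(self, instance):
        x, y = instance
        r = youden_optimal_cutoff(x, y)
        assert r.j == pytest.approx(oracles.brute_force_youden(x, y), abs=1e-9)
        assert r.j >= -1e-12

    def test_sign_flip_swaps_direction(self, rng):
        x, y = random_instance(rng)
        r1 = youden_optimal_cutoff(x, y)
        r2 = youden_optimal_cutoff(-x, y)
        assert r2.j == pytest.approx(r1.j)
        if r1.direction is not None:
            assert {r1.direction, r2.direction} == {"hi", "lo"}
        assert r2.auroc == pytest.approx(1 - r1.auroc)

    def test_constant_levels_flagged(self):
        r = youden_optimal_cutoff([2.0, 2.0, 2.0, 2.0], [1, 0, 1, 0])
        assert r.direction is None and r.j == 0.0

    def test_independent_roc_cross_check(self, rng):
        # sklearn's ROC machinery as an external referee for AUROC
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            x, y = random_instance(rng)
            assert auroc(x, y) == pytest.approx(roc_auc_score(y, x), abs=1e-12)


class TestSelectDeps:
    def test_threshold_one_keeps_only_perfect(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 10)), columns=[f"P{i}" for i in range(10)])
        y = np.array([True] * 6 + [False] * 14)
        m["P0"] = np.where(y, 10.0, 0.0) + rng.normal(0, 0.01, 20)
        deps = select_deps(m, y, auroc_min=1.0)
        assert deps == [] or all(d.auroc == 1.0 for d in deps)
        deps_perfect = select_deps(m[["P0"]], y, auroc_min=0.99)
        assert [d.protein_id for d in deps_perfect] == ["P0"]

    def test_sorted_by_auroc_then_id(self, default_trial):
        c = default_trial.cohort
        act = c["arm"] == "high_dose"
        flags = ep.compute_endpoints(c).set_index("patient_id").loc[
            c.loc[act, "patient_id"], "easi50_wk4"].astype(bool).to_numpy()
        deps = select_deps(default_trial.proteome.loc[c.loc[act, "patient_id"]], flags)
        aucs = [d.auroc for d in deps]
        assert aucs == sorted(aucs, reverse=True)
        assert all(a > 0.7 for a in aucs)

    def test_null_false_selection_rate_matches_permutation_oracle(self):
        # pure-noise screening: fresh-noise simulation vs label permutation
        rng = np.random.default_rng(77)
        n, p, reps = 20, 60, 40
        y = np.array([True] * 6 + [False] * 14)
        sim_counts = []
        perm_counts = []
        for _ in range(reps):
            m = pd.DataFrame(rng.normal(size=(n, p)))
            m.columns = [f"P{i}" for i in range(p)]
            sim_counts.append(len(select_deps(m, y)))
            perm_counts.append(len(select_deps(m, rng.permutation(y))))
        diff = np.mean(sim_counts) - np.mean(perm_counts)
        se = np.sqrt((np.var(sim_counts) + np.var(perm_counts)) / reps)
        assert abs(diff) < 2 * se + 1e-9


class TestConfusion:
    def _cut(self, direction="hi", cutoff=5.0):
        return CutoffResult("P", direction, cutoff, 0.5, 0.8, 0.7, 0.8)

    @pytest.mark.parametrize(
        "table,ppv,npv",
        [
            (ContingencyTable(4, 0, 1, 15), 1.000, 0.938),
            (ContingencyTable(4, 1, 1, 14), 0.800, 0.933),
        ],
    )
    def test_printed_ppv_npv_rows(self, table, ppv, npv):
        assert table.ppv == pytest.approx(ppv, abs=5e-4)
        assert table.npv == pytest.approx(npv, abs=5e-4)

    def test_all_responders_favorable(self):
        levels = [10, 9, 8, 1, 2, 3]
        y = [1, 1, 1, 0, 0, 0]
        table, ppv, npv = stratify_and_confusion(levels, self._cut(), y)
        assert (table.a, table.b, table.c, table.d) == (3, 0, 0, 3)
        assert ppv == 1.0 and npv == 1.0

    def test_boundary_value_goes_to_favorable_side(self):
        table, _, _ = stratify_and_confusion([5.0, 4.9], self._cut("hi", 5.0), [1, 0])
        assert table.a == 1 and table.d == 1
        table, _, _ = stratify_and_confusion([5.0, 5.1], self._cut("lo", 5.0), [1, 0])
        assert table.a == 1 and table.d == 1

    def test_metrics_algebraically_consistent(self, rng):
        x, y = random_instance(rng)
        r = youden_optimal_cutoff(x, y)
        if r.direction is None:
            return
        table, ppv, npv = stratify_and_confusion(x, r, y)
        n1 = y.sum()
        n0 = (~y).sum()
        sens = table.a / n1
        spec = table.d / n0
        if r.direction == "hi":
            assert sens == pytest.approx(r.sensitivity)
            assert spec == pytest.approx(r.specificity)
        assert table.n == len(x)


class TestOddsRatio:
    def test_zero_cell_table_matches_printed_values(self):
        r = odds_ratio_ha(ContingencyTable(4, 0, 1, 15))
        assert r.corrected
        assert r.odds_ratio == pytest.approx(93.0, abs=0.05)
        assert r.ci_low == pytest.approx(3.2, abs=0.05)
        assert r.ci_high == pytest.approx(2699.7, abs=0.5)

    def test_no_zero_cell_table_matches_printed_values(self):
        r = odds_ratio_ha(ContingencyTable(4, 1, 1, 14))
        assert not r.corrected
        assert r.odds_ratio == pytest.approx(56.0, abs=0.05)
        assert r.ci_low == pytest.approx(2.8, abs=0.05)
        assert r.ci_high == pytest.approx(1109.4, abs=0.5)

    def test_symmetric_table_is_unity(self):
        assert odds_ratio_ha(ContingencyTable(1, 1, 1, 1)).odds_ratio == 1.0

    def test_correction_never_fires_on_positive_tables(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 12, 4)
            r = odds_ratio_ha(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert not r.corrected
            assert r.odds_ratio == pytest.approx((a * d) / (b * c))
            assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_empty_outcome_margin_raises(self):
        with pytest.raises(ValueError):
            odds_ratio_ha(ContingencyTable(0, 3, 0, 5))


class TestFisher:
    def test_unit_table(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_reconstructed_marker_table(self):
        p = fisher_exact(ContingencyTable(4, 0, 1, 15))
        assert p == pytest.approx(oracles.fisher_two_sided(4, 0, 1, 15), rel=1e-9)
        assert p == pytest.approx(0.00103, abs=2e-5)

    def test_small_tables_match_enumeration(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 5, 4))
            if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
                oracles.fisher_two_sided(a, b, c, d), rel=1e-7
            )


class TestBenefit:
    @pytest.mark.parametrize(
        "pe,pi,flag",
        [(0.003, 0.004, True), (0.049, 0.051, False), (0.05, 0.01, False), (0.0, 0.0, True)],
    )
    def test_dual_strict_threshold(self, pe, pi, flag):
        assert benefit_indicator(pe, pi) is flag

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            benefit_indicator(-0.1, 0.5)


class TestStratumReport:
    def _trial(self):
        cfg = TrialConfig(
            planted_markers=(PlantedMarker(2, "hi", 0.3, 3.5),),
            responsive_fraction=0.3, n_proteins=10, seed=19,
        )
        return simulate_trial(cfg)

    def test_planted_marker_yields_benefit(self):
        trial = self._trial()
        endpoints = ep.compute_endpoints(trial.cohort)
        act = endpoints["arm"] == "high_dose"
        flags = endpoints.loc[act, "easi50_wk4"].astype(bool).to_numpy()
        levels_act = trial.proteome.loc[endpoints.loc[act, "patient_id"], "P0002"]
        cut = youden_optimal_cutoff(levels_act.to_numpy(), flags, protein_id="P0002")
        report = stratum_report(endpoints, trial.proteome["P0002"], cut)
        assert report.benefit
        assert report.label == "P0002^hi"
        assert report.delta_easi.mean_diff < -30
        assert report.auroc > 0.7

    def test_everyone_stratum_is_full_bas(self):
        trial = self._trial()
        endpoints = ep.compute_endpoints(trial.cohort)
        cut = CutoffResult("P0002", "hi", -1.0, 0.0, 1.0, 0.0, 0.5)  # below all levels
        report = stratum_report(endpoints, trial.proteome["P0002"], cut)
        assert report.pct_bas == pytest.approx(100.0)

    def test_stratum_missing_an_arm_reports_no_benefit(self):
        trial = self._trial()
        endpoints = ep.compute_endpoints(trial.cohort)
        # favorable stratum restricted to placebo patients only
        placebo_ids = endpoints.loc[endpoints["arm"] == "placebo", "patient_id"]
        levels = pd.Series(0.0, index=trial.proteome.index, name="P0002")
        levels.loc[placebo_ids] = 10.0
        cut = CutoffResult("P0002", "hi", 5.0, 0.0, 0.5, 0.5, 0.5)
        report = stratum_report(endpoints, levels, cut)
        assert report.delta_easi is None
        assert report.benefit is False
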