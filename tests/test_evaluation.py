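"""Evaluation metrics checked against brute-force / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioscreen.cohort import EchoReport
from cardioscreen.evaluation import (
    OperatingPoint,
    UndefinedMetricError,
    auroc,
    bootstrap_ci,
    cohens_kappa,
    ece,
    evaluate_predictions,
    fleiss_kappa,
    majority_vote,
    mcnemar,
    sens_spec,
    sensitivity_by_lesion,
    site_combination_table,
    threshold_for_specificity,
    youden,
)


def auroc_bruteforce(scores, labels):
    """Pairwise enumeration oracle: P(pos > neg) + half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_four_point_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert abs(auroc(scores, labels) - auroc_bruteforce(scores, labels)) < 1e-12

    def test_null_behaviour_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        assert abs(auroc(scores, labels) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])


class TestSensSpec:
    SCORES = np.array([0.9, 0.6, 0.3, 0.2])
    LABELS = np.array([1, 1, 0, 0])

    def test_threshold_zero_refers_everyone(self):
        sens, spec, _ = sens_spec(self.SCORES, self.LABELS, OperatingPoint(0.0))
        assert sens == 1.0 and spec == 0.0

    def test_threshold_above_max(self):
        sens, spec, _ = sens_spec(self.SCORES, self.LABELS, OperatingPoint(0.95))
        assert sens == 0.0 and spec == 1.0

    def test_hand_counted_example(self):
        sens, spec, conf = sens_spec(self.SCORES, self.LABELS, OperatingPoint(0.675))
        assert sens == 0.5 and spec == 1.0
        assert conf == {"tp": 1, "fp": 0, "tn": 2, "fn": 1}

    def test_sweep_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        sens_prev, spec_prev = 1.0, 0.0
        for thr in np.linspace(0, 1, 21):
            sens, spec, _ = sens_spec(scores, labels, OperatingPoint(thr))
            assert sens <= sens_prev + 1e-12
            assert spec >= spec_prev - 1e-12
            sens_prev, spec_prev = sens, spec


class TestThresholdForSpecificity:
    def test_enumerated_example(self):
        scores = np.array([0.1, 0.2, 0.3, 0.9, 0.8, 0.95])
        labels = np.array([0, 0, 0, 0, 1, 1])
        op = threshold_for_specificity(scores, labels, 0.75)
        sens, spec, _ = sens_spec(scores, labels, op)
        assert 0.3 < op.threshold <= 0.8
        assert spec == 0.75 and sens == 1.0

    def test_target_zero(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        op = threshold_for_specificity(scores, labels, 0.0)
        sens, _, _ = sens_spec(scores, labels, op)
        assert sens == 1.0

    def test_target_one_separable(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        op = threshold_for_specificity(scores, labels, 1.0)
        _, spec, _ = sens_spec(scores, labels, op)
        assert spec == 1.0

    def test_unachievable_target_warns_and_refuses_all(self):
        scores = np.array([1.0, 1.0, 1.0, 0.5])
        labels = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="not achievable"):
            op = threshold_for_specificity(scores, labels, 0.99)
        assert op.threshold >= 1.0


class TestEce:
    def test_perfectly_confident_and_correct(self):
        val, _ = ece(np.ones(5), np.ones(5))
        assert val == 0.0

    def test_two_bin_hand_example(self):
        val, bins = ece([0.9, 0.9, 0.1, 0.1], [1, 0, 0, 0], n_bins=2)
        assert abs(val - 0.25) < 1e-12
        assert bins["count"].sum() == 4

    def test_calibrated_by_construction_null(self):
        rng = np.random.default_rng(3)
        probs = rng.random(10_000)
        labels = (rng.random(10_000) < probs).astype(int)
        val, bins = ece(probs, labels)
        assert val <= 0.03
        assert bins["count"].sum() == 10_000

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ece([], [])


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi, skipped = bootstrap_ci(lambda x: 1.23, (np.arange(50),), n_boot=100, seed=0)
        assert lo == hi == 1.23 and skipped == 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.random(100)
        a = bootstrap_ci(np.mean, (x,), n_boot=200, seed=7)
        b = bootstrap_ci(np.mean, (x,), n_boot=200, seed=7)
        assert a == b

    def test_degenerate_resamples_counted(self):
        scores = np.array([0.2, 0.8])
        labels = np.array([0, 1])
        lo, hi, skipped = bootstrap_ci(auroc, (scores, labels), n_boot=50, seed=1)
        assert skipped > 0  # half of 2-point resamples are single-class


class TestMcnemar:
    def mcnemar_oracle(self, b01, b10):
        n = b01 + b10
        if n == 0:
            return 1.0
        k = max(b01, b10)
        return min(1.0, 2.0 * sum(stats.binom.pmf(i, n, 0.5) for i in range(k, n + 1)))

    def test_identical_raters(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert mcnemar(a, a) == (0, 0, 1.0)

    def test_nine_two_example(self):
        a = np.concatenate([np.ones(9), np.zeros(2), np.ones(5)]).astype(bool)
        b = np.concatenate([np.zeros(9), np.ones(2), np.ones(5)]).astype(bool)
        b01, b10, p = mcnemar(a, b)
        assert (b01, b10) == (9, 2)
        assert abs(p - 0.0654) < 5e-4

    def test_symmetry(self):
        a = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        b = np.array([0, 1, 1, 0, 0, 0], dtype=bool)
        b01, b10, p = mcnemar(a, b)
        b01r, b10r, pr = mcnemar(b, a)
        assert (b01, b10) == (b10r, b01r) and p == pr

    def test_matches_exact_binomial_oracle(self):
        for b01 in range(0, 13):
            for b10 in range(0, 13):
                flags_a = np.concatenate([np.ones(b01), np.zeros(b10)]).astype(bool)
                flags_b = ~flags_a
                _, _, p = mcnemar(flags_a, flags_b)
                assert abs(p - self.mcnemar_oracle(b01, b10)) < 1e-10, (b01, b10)


class TestKappa:
    def test_identical_ratings(self):
        r = np.array([0, 1, 0, 1, 1])
        assert cohens_kappa(r, r) == 1.0

    def test_hand_computed_table(self):
        # a=20 both-positive, b=c=5 discordant, d=20 both-negative
        r1 = np.concatenate([np.ones(20), np.ones(5), np.zeros(5), np.zeros(20)])
        r2 = np.concatenate([np.ones(20), np.zeros(5), np.ones(5), np.zeros(20)])
        assert abs(cohens_kappa(r1, r2) - 0.6) < 1e-12  # p_o=0.8, p_e=0.5

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(5)
        r1 = rng.integers(0, 2, 5000)
        r2 = rng.integers(0, 2, 5000)
        assert abs(cohens_kappa(r1, r2)) < 0.05

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    def test_fleiss_perfect_agreement(self):
        ratings = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0]])
        assert abs(fleiss_kappa(ratings) - 1.0) < 1e-12

    def test_fleiss_two_raters_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        ratings = rng.integers(0, 2, (30, 2))
        n, m = ratings.shape
        counts = np.stack([(ratings == 0).sum(1), (ratings == 1).sum(1)], axis=1)
        p_i = ((counts * (counts - 1)).sum(1)) / (m * (m - 1))
        p_bar = p_i.mean()
        p_cat = counts.sum(0) / (n * m)
        p_e = (p_cat ** 2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert abs(fleiss_kappa(ratings) - expected) < 1e-10

    def test_fleiss_null_mean_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(1000):
            ratings = rng.integers(0, 2, (6, 14))
            try:
                vals.append(fleiss_kappa(ratings))
            except UndefinedMetricError:
                continue
        assert abs(np.mean(vals)) < 0.05

    def test_fleiss_single_category_rejected(self):
        with pytest.raises(UndefinedMetricError):
            fleiss_kappa(np.ones((5, 3), dtype=int))


class TestVotesAndYouden:
    @pytest.mark.parametrize("votes,expected", [
        ([True, False, True], True),
        ([True, False], True),  # tie biased to refer
        ([False, False, False], False),
    ])
    def test_majority_vote(self, votes, expected):
        assert majority_vote(votes) is expected

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    @pytest.mark.parametrize("sens,spec,expected", [(1, 1, 1), (0.5, 0.5, 0.0), (0.72, 0.82, 0.54)])
    def test_youden(self, sens, spec, expected):
        assert abs(youden(sens, spec) - expected) < 1e-12


def _toy_preds_and_echos():
    """Six significant patients (various lesions) + four controls."""
    echos = {
        "s1": EchoReport.from_grades(AS=3), "s2": EchoReport.from_grades(AS=3),
        "s3": EchoReport.from_grades(AS=2), "s4": EchoReport.from_grades(MR=2),
        "s5": EchoReport.from_grades(MR=3, AS=1), "s6": EchoReport.from_grades(TR=2),
        "c1": EchoReport.from_grades(), "c2": EchoReport.from_grades(MR=1),
        "c3": EchoReport.from_grades(), "c4": EchoReport.from_grades(),
    }
    rows = []
    probs = {"s1": 0.95, "s2": 0.9, "s3": 0.8, "s4": 0.4, "s5": 0.85, "s6": 0.7,
             "c1": 0.1, "c2": 0.3, "c3": 0.2, "c4": 0.15}
    for pid, pr in probs.items():
        rows.append({"id": pid, "prob_fused": pr, "label": int(pid.startswith("s")),
                     "prob_A": pr, "prob_P": pr * 0.5, "prob_T": pr * 0.8, "prob_M": pr * 0.9})
    return pd.DataFrame(rows), echos


class TestTables:
    def test_sensitivity_by_lesion_cells(self):
        preds, echos = _toy_preds_and_echos()
        op = OperatingPoint(0.675)
        table = sensitivity_by_lesion(preds, echos, op, n_boot=50)
        assert table.loc[("AS", "severe"), "sensitivity"] == 1.0
        assert table.loc[("AS", "severe"), "n"] == 2
        assert table.loc[("MR", "moderate"), "sensitivity"] == 0.0
        # partition: AS cells cover all qualifying AS patients exactly once
        as_n = table.loc["AS"]["n"].sum()
        assert as_n == 4  # s1, s2 severe; s3 moderate; s5 mild

    def test_isolated_counts_are_subsets(self):
        preds, echos = _toy_preds_and_echos()
        op = OperatingPoint(0.675)
        all_t = sensitivity_by_lesion(preds, echos, op, isolated_only=False, n_boot=20)
        iso_t = sensitivity_by_lesion(preds, echos, op, isolated_only=True, n_boot=20)
        assert (iso_t["n"] <= all_t["n"]).all()
        # s5 has MR severe + AS mild, so it is not isolated MR
        assert iso_t.loc[("MR", "severe"), "n"] == 0
        assert all_t.loc[("MR", "severe"), "n"] == 1

    def test_empty_cell_marked_undefined(self):
        preds, echos = _toy_preds_and_echos()
        table = sensitivity_by_lesion(preds, echos, OperatingPoint(0.5), n_boot=20)
        assert table.loc[("TS", "severe"), "n"] == 0
        assert np.isnan(table.loc[("TS", "severe"), "sensitivity"])

    def test_site_combinations(self):
        preds, echos = _toy_preds_and_echos()
        table = site_combination_table(preds, echos, [("A",), ("M",), ("A", "M"), ("A", "P", "T", "M")],
                                       target_spec=0.75)
        for combo in table.index:
            assert table.loc[combo, "specificity"] >= 0.75
        # singleton combo reproduces single-site scores: fused == prob_A
        op_a = threshold_for_specificity(preds["prob_A"], preds["label"], 0.75)
        sens_a, _, _ = sens_spec(preds["prob_A"], preds["label"], op_a)
        assert table.loc["A", "sensitivity"] == sens_a

    def test_fixed_threshold_fusion_monotone_in_combo_inclusion(self):
        preds, _ = _toy_preds_and_echos()
        thr = 0.5
        for sub, sup in [(("A",), ("A", "M")), (("A", "M"), ("A", "P", "T", "M"))]:
            f_sub = preds[[f"prob_{s}" for s in sub]].max(axis=1)
            f_sup = preds[[f"prob_{s}" for s in sup]].max(axis=1)
            assert ((f_sup >= thr) | ~(f_sub >= thr)).all()  # refer set only grows


class TestEvaluatePredictions:
    def test_report_shape_and_summary(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 300)
        scores = np.clip(labels * 0.5 + rng.normal(0.3, 0.2, 300), 0, 1)
        rep = evaluate_predictions(scores, labels, n_boot=100, seed=0)
        d = rep.to_dict()
        assert 0.5 < d["auroc"] <= 1.0
        assert d["auroc_ci"][0] <= d["auroc"] <= d["auroc_ci"][1]
        assert sum(d["confusion"].values()) == 300
        assert sum(b["count"] for b in d["reliability_bins"]) == 300
        assert "AUROC" in rep.summary()
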