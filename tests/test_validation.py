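import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mirmeta import (
    GRADE_SCORE_MODEL,
    HCC_RISK_MODEL,
    PairedExpression,
    RiskModel,
    classify_deregulated,
    ddct_fold_change,
    filter_and_log2,
    km_logrank,
    optimal_cutoff_logrank,
    paired_de_test,
    risk_score,
    roc_auc,
    summarize_folds,
)


def ct_row(patient, mirna, tt, tn, rt, rn):
    return {"patient": patient, "mirna": mirna, "ct_target_tumor": tt,
            "ct_target_normal": tn, "ct_ref_tumor": rt, "ct_ref_normal": rn}


class TestDdct:
    def test_worked_example(self):
        # ddCt = (22-18) - (25-18) = -3 -> fold 2^3 = 8
        ct = pd.DataFrame([ct_row("P1", "miR-21", 22, 25, 18, 18)])
        assert ddct_fold_change(ct).loc["P1", "miR-21"] == pytest.approx(8.0)

    def test_identical_quadruples_give_unit_fold(self):
        ct = pd.DataFrame([ct_row("P1", "miR-21", 20, 20, 18, 18)])
        assert ddct_fold_change(ct).loc["P1", "miR-21"] == pytest.approx(1.0)

    def test_swapping_tissues_gives_reciprocal(self):
        ct = pd.DataFrame([ct_row("P1", "miR-21", 22, 25, 17, 19)])
        swapped = pd.DataFrame([ct_row("P1", "miR-21", 25, 22, 19, 17)])
        f = ddct_fold_change(ct).loc["P1", "miR-21"]
        g = ddct_fold_change(swapped).loc["P1", "miR-21"]
        assert f * g == pytest.approx(1.0)

    def test_shift_invariance(self):
        # adding a constant to all four Ct values of a patient changes nothing
        ct = pd.DataFrame([ct_row("P1", "miR-21", 22, 25, 17, 19)])
        shifted = pd.DataFrame([ct_row("P1", "miR-21", 25.5, 28.5, 20.5, 22.5)])
        assert ddct_fold_change(ct).loc["P1", "miR-21"] == pytest.approx(
            ddct_fold_change(shifted).loc["P1", "miR-21"])

    def test_missing_component_marks_cell_missing(self):
        ct = pd.DataFrame([ct_row("P1", "miR-21", 22, np.nan, 18, 18)])
        assert np.isnan(ddct_fold_change(ct).loc["P1", "miR-21"])

    def test_summary_fold_is_geometric_mean(self):
        ct = pd.DataFrame([ct_row("P1", "miR-21", 22, 25, 18, 18),   # fold 8
                           ct_row("P2", "miR-21", 24, 25, 18, 18)])  # fold 2
        summary = summarize_folds(ddct_fold_change(ct))
        assert summary["miR-21"] == pytest.approx(4.0)


class TestClassify:
    def test_inclusive_thresholds(self):
        calls = classify_deregulated(pd.Series({"a": 2.0, "b": 0.5, "c": 1.2}))
        assert calls.tolist() == ["up", "down", "unchanged"]

    def test_scalar_input(self):
        assert classify_deregulated(3.1) == "up"

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError):
            classify_deregulated(pd.Series({"a": 0.0}))


def paired(tumor, normal, **kw):
    return PairedExpression(tumor=pd.DataFrame(tumor), normal=pd.DataFrame(normal), **kw)


class TestFilterAndLog2:
    def test_missing_threshold_is_exclusive(self):
        n = 100
        t = pd.DataFrame({"keep": np.ones(n), "drop": np.ones(n)})
        t.loc[:9, "keep"] = np.nan   # exactly 10% missing -> kept
        t.loc[:10, "drop"] = np.nan  # 11% missing -> dropped
        expr = paired(t, pd.DataFrame(np.ones((n, 2)), columns=["keep", "drop"]))
        out = filter_and_log2(expr)
        assert out.mirnas == ["keep"]
        assert out.log2_transformed

    def test_pseudocount_zero_maps_one_to_zero(self):
        expr = paired({"m": [1.0, 1.0, 1.0]}, {"m": [1.0, 1.0, 1.0]})
        out = filter_and_log2(expr, pseudocount=0.0)
        assert (out.tumor["m"] == 0).all()

    def test_all_dropped_raises(self):
        t = pd.DataFrame({"m": [np.nan] * 10})
        expr = paired(t, pd.DataFrame({"m": np.ones(10)}))
        with pytest.raises(ValueError):
            filter_and_log2(expr)


class TestPairedTest:
    def test_no_signal_gives_p_one_and_zero_median(self):
        expr = paired({"m": [1.0, 2.0, 4.0, 8.0]}, {"m": [1.0, 2.0, 4.0, 8.0]})
        res = paired_de_test(expr).iloc[0]
        assert res["p_value"] == 1.0
        assert res["median_log2_diff"] == 0.0

    def test_consistent_shift_n11_attains_minimal_signed_rank_p(self):
        # all 11 differences positive (and distinct, so the exact null
        # enumeration applies): two-sided p = 2 / 2^11
        vals = np.arange(1, 12, dtype=float)
        diffs = 1.0 + 0.01 * vals
        expr = paired({"m": 2.0 ** (vals + diffs)}, {"m": 2.0 ** vals})
        res = paired_de_test(expr).iloc[0]
        assert res["p_value"] == pytest.approx(2 / 2 ** 11)
        assert res["median_log2_diff"] == pytest.approx(np.median(diffs))

    def test_fewer_than_three_pairs_rejected(self):
        expr = paired({"m": [1.0, 2.0]}, {"m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="m"):
            paired_de_test(expr)

    def test_ttest_agrees_in_direction(self):
        rng = np.random.default_rng(0)
        base = 2.0 ** rng.normal(6, 1, size=20)
        jitter = 2.0 ** rng.normal(0, 0.2, size=20)
        expr = paired({"m": base * 4 * jitter}, {"m": base})
        w = paired_de_test(expr, method="wilcoxon").iloc[0]
        t = paired_de_test(expr, method="ttest").iloc[0]
        assert w["p_value"] < 0.05 and t["p_value"] < 0.05

    def test_power_against_planted_twofold_shift(self):
        from mirmeta.simulate import ExprSimParams, simulate_paired_expression
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            params = ExprSimParams(n_pairs=50, log2_fold_changes={"m": 1.0},
                                   noise_sd=0.5, seed=seed)
            expr, _ = simulate_paired_expression(params)
            if paired_de_test(expr).iloc[0]["p_value"] < 0.01:
                hits += 1
        assert hits >= 0.95 * n_sim


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example_with_tie(self):
        res = roc_auc([1, 2, 2, 3], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.875)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 20], [0, 0, 1, 1]).auc == 1.0

    def test_label_flip_symmetry(self):
        scores = [3.0, 1.0, 2.5, 0.5, 2.0]
        labels = np.array([1, 0, 1, 0, 0])
        assert roc_auc(scores, labels).auc == pytest.approx(
            1 - roc_auc(scores, 1 - labels).auc)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 10, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestRiskScore:
    def test_unit_expression_scores_zero(self):
        expr = pd.DataFrame(1.0, index=["s1"], columns=list(HCC_RISK_MODEL.coefficients))
        assert risk_score(expr).iloc[0] == pytest.approx(0.0)

    def test_single_coefficient_contribution(self):
        expr = pd.DataFrame(1.0, index=["s1"], columns=list(HCC_RISK_MODEL.coefficients))
        expr.loc["s1", "miR-221"] = 2.0
        assert risk_score(expr).iloc[0] == pytest.approx(0.180)

    def test_doubling_negative_weight_mirna_lowers_score(self):
        expr = pd.DataFrame(2.0, index=["s1", "s2"],
                            columns=list(HCC_RISK_MODEL.coefficients))
        expr.loc["s2", "miR-130a"] = 4.0
        scores = risk_score(expr)
        assert scores["s2"] - scores["s1"] == pytest.approx(-0.185)

    def test_linearity_in_log2_expression(self):
        rng = np.random.default_rng(3)
        cols = list(GRADE_SCORE_MODEL.coefficients)
        expr = pd.DataFrame(2.0 ** rng.normal(5, 1, size=(4, len(cols))),
                            index=list("abcd"), columns=cols)
        scaled = expr.copy()
        scaled["miR-21"] *= 8.0
        delta = risk_score(scaled, GRADE_SCORE_MODEL) - risk_score(expr, GRADE_SCORE_MODEL)
        np.testing.assert_allclose(delta, 0.0763 * 3, rtol=1e-10)

    def test_missing_model_mirna_named_in_error(self):
        expr = pd.DataFrame(1.0, index=["s1"], columns=["miR-221"])
        with pytest.raises(KeyError, match="miR-223"):
            risk_score(expr)

    def test_custom_model_validation(self):
        with pytest.raises(ValueError):
            RiskModel(coefficients={})
        with pytest.raises(ValueError):
            RiskModel(coefficients={"m": np.inf})


def hand_logrank_chi2(time, event, group):
    """Textbook two-group log-rank: sum (O-E) with hypergeometric variance."""
    time, event, group = map(np.asarray, (time, event, group))
    o1 = e1 = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestSurvival:
    def test_identical_groups_have_null_chi_square(self):
        time = [5, 10, 15, 5, 10, 15]
        event = [1, 1, 0, 1, 1, 0]
        res = km_logrank(time, event, [0, 0, 0, 1, 1, 1])
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_worked_six_patient_table(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 0, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        res = km_logrank(time, event, group)
        assert res.chi_square == pytest.approx(hand_logrank_chi2(time, event, group))

    def test_km_curves_step_down_at_events(self):
        res = km_logrank([2, 4, 6, 8], [1, 1, 1, 1], [0, 0, 1, 1])
        times, surv = res.curves[0]
        assert surv[0] == 1.0 and surv[-1] == 0.0

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_power_under_strong_hazard_ratio(self):
        from mirmeta.simulate import SurvSimParams, simulate_survival
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            surv, _ = simulate_survival(SurvSimParams(
                n=200, log_hazard_ratio=np.log(3.0), seed=seed))
            groups = (surv["marker"] > surv["marker"].median()).astype(int)
            res = km_logrank(surv["time_months"], surv["event"], groups)
            if res.p_value < 0.01:
                hits += 1
        assert hits >= 0.90 * n_sim


class TestOptimalCutoff:
    def survival_frame(self, marker, time, event):
        return pd.DataFrame({"time_months": time, "event": event, "marker": marker})

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        n = 60
        marker = rng.normal(size=n)
        time = rng.exponential(20, size=n)
        event = rng.integers(0, 2, size=n)
        event[0:2] = 1
        surv = self.survival_frame(marker, time, event)
        cut, chi2, p = optimal_cutoff_logrank(surv)
        # independent enumeration over all admissible midpoints
        best = (None, -np.inf, None)
        distinct = np.unique(marker)
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            c = (lo + hi) / 2
            high = marker > c
            if high.sum() < 0.1 * n or (~high).sum() < 0.1 * n:
                continue
            r = logrank_test(time[~high], time[high],
                            event_observed_A=event[~high],
                            event_observed_B=event[high])
            if r.test_statistic > best[1]:
                best = (c, r.test_statistic, r.p_value)
        assert cut == pytest.approx(best[0])
        assert chi2 == pytest.approx(best[1])

    def test_reported_chi_square_consistent_with_km_logrank(self):
        rng = np.random.default_rng(9)
        surv = self.survival_frame(rng.normal(size=50),
                                   rng.exponential(10, size=50),
                                   np.ones(50, dtype=int))
        cut, chi2, _ = optimal_cutoff_logrank(surv)
        groups = (surv["marker"] > cut).astype(int)
        res = km_logrank(surv["time_months"], surv["event"], groups)
        assert chi2 == pytest.approx(res.chi_square)

    def test_bimodal_marker_cut_falls_between_modes(self):
        rng = np.random.default_rng(10)
        n = 40
        marker = np.r_[rng.normal(0, 0.3, n // 2), rng.normal(5, 0.3, n // 2)]
        # high-marker mode has 40x hazard
        time = rng.exponential(np.where(marker > 2.5, 0.5, 20))
        surv = self.survival_frame(marker, np.maximum(time, 0.01),
                                   np.ones(n, dtype=int))
        cut, _, _ = optimal_cutoff_logrank(surv)
        assert 1.5 < cut < 3.5

    def test_two_point_marker_returns_single_admissible_cutoff(self):
        surv = self.survival_frame([0.0] * 5 + [1.0] * 5,
                                   [2, 3, 4, 5, 6, 1, 1, 2, 2, 3],
                                   [1] * 10)
        cut, _, _ = optimal_cutoff_logrank(surv)
        assert cut == pytest.approx(0.5)

    def test_min_group_fraction_excludes_extreme_cuts(self):
        marker = np.r_[0.0, np.ones(19)]
        surv = self.survival_frame(marker, np.arange(1, 21, dtype=float),
                                   np.ones(20, dtype=int))
        with pytest.raises(ValueError):
            optimal_cutoff_logrank(surv, min_group_fraction=0.10)

    def test_naive_minimum_p_is_anticonservative_under_null(self):
        # the scanned minimum p rejects far more than its nominal level
        rng = np.random.default_rng(11)
        n, rejections, n_sim = 24, 0, 50
        for _ in range(n_sim):
            surv = self.survival_frame(rng.normal(size=n),
                                       rng.exponential(10, size=n),
                                       np.ones(n, dtype=int))
            _, _, p = optimal_cutoff_logrank(surv)
            rejections += p < 0.05
        assert rejections / n_sim > 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sim)
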