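import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairshift import fairness_metrics as fm
from fairshift.grid_store import ValidationError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pair_counting_auroc(scores, labels):
    """Exhaustive Mann-Whitney pair statistic."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def sweep_f1_threshold(scores, labels):
    """Exhaustive sweep over every unique score."""
    best_t, best_f1 = None, -1.0
    n_pos = sum(labels)
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        f1 = 2 * tp / (2 * tp + fp + (n_pos - tp))
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


@st.composite
def score_label_instances(draw, min_size=4, max_size=50):
    n = draw(st.integers(min_size, max_size))
    scores = draw(st.lists(st.integers(0, 20).map(lambda k: k / 20),
                           min_size=n, max_size=n))
    labels = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    return scores, labels


class TestAuroc:
    def test_textbook_instance(self):
        assert fm.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        assert fm.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert fm.auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_single_class_yields_undefined_marker(self):
        assert math.isnan(fm.auroc([0.1, 0.9], [1, 1]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score_label_instances())
    def test_matches_exhaustive_pair_counting(self, instance):
        scores, labels = instance
        if 0 < sum(labels) < len(labels):
            assert fm.auroc(scores, labels) == pytest.approx(
                pair_counting_auroc(scores, labels), abs=1e-12)


class TestF1Threshold:
    def test_small_instance(self):
        assert fm.f1_optimal_threshold([0.2, 0.6, 0.9], [0, 1, 1]) == 0.6

    def test_all_positive_labels_choose_smallest_score(self):
        assert fm.f1_optimal_threshold([0.3, 0.7, 0.5], [1, 1, 1]) == 0.3

    def test_no_positives_is_an_error(self):
        with pytest.raises(ValidationError):
            fm.f1_optimal_threshold([0.2, 0.6], [0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score_label_instances())
    def test_matches_exhaustive_sweep(self, instance):
        scores, labels = instance
        if sum(labels) > 0:
            assert fm.f1_optimal_threshold(scores, labels) == pytest.approx(
                sweep_f1_threshold(scores, labels))


class TestConfusionRates:
    def test_perfect_and_inverted_classifiers(self):
        r = fm.confusion_rates([0.9, 0.1], [1, 0], 0.5)
        assert (r.tpr, r.tnr, r.fpr, r.fnr) == (1, 1, 0, 0)
        r = fm.confusion_rates([0.9, 0.1], [0, 1], 0.5)
        assert (r.fpr, r.fnr) == (1, 1)

    def test_empty_class_rates_are_undefined(self):
        r = fm.confusion_rates([0.9, 0.1], [0, 0], 0.5)
        assert math.isnan(r.tpr) and math.isnan(r.fnr)
        assert r.fpr == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(score_label_instances(), st.integers(0, 20))
    def test_rate_complements_sum_to_one(self, instance, t20):
        scores, labels = instance
        r = fm.confusion_rates(scores, labels, t20 / 20)
        if not math.isnan(r.tpr):
            assert r.tpr + r.fnr == pytest.approx(1.0, abs=1e-12)
        if not math.isnan(r.tnr):
            assert r.tnr + r.fpr == pytest.approx(1.0, abs=1e-12)


class TestEce:
    def test_perfectly_calibrated_constant_score(self):
        scores = [0.7] * 10
        labels = [1] * 7 + [0] * 3
        assert fm.ece(scores, labels, 10) == pytest.approx(0.0, abs=1e-12)

    def test_maximally_miscalibrated(self):
        assert fm.ece([0.9] * 5, [0] * 5, 10) == pytest.approx(0.9)

    def test_matches_brute_force_bin_accounting(self):
        rng = np.random.default_rng(7)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        n_bins = 5
        expected = 0.0
        for b in range(n_bins):
            lo, hi = b / n_bins, (b + 1) / n_bins
            members = [i for i, s in enumerate(scores)
                       if lo <= s < hi or (b == n_bins - 1 and s == 1.0)]
            if members:
                conf = np.mean([scores[i] for i in members])
                acc = np.mean([labels[i] for i in members])
                expected += len(members) / 20 * abs(conf - acc)
        assert fm.ece(scores, labels, n_bins) == pytest.approx(expected, abs=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            fm.ece([], [], 10)


class TestGroupMetrics:
    def test_identical_groups_get_identical_rates(self, pred_factory):
        pred = pred_factory([0.2, 0.8, 0.2, 0.8], [0, 1, 0, 1],
                            ["f", "f", "m", "m"])
        out = fm.group_metrics(pred, "sex", threshold_policy=0.5)
        assert out["f"].tpr == out["m"].tpr
        assert out["f"].fpr == out["m"].fpr
        assert out["f"].ece == out["m"].ece

    def test_threshold_is_shared_across_groups(self, pred_factory):
        # group f would choose a different threshold alone; the pooled one rules
        pred = pred_factory([0.3, 0.9, 0.6, 0.2], [1, 1, 1, 0],
                            ["f", "f", "m", "m"])
        pooled_t = fm.f1_optimal_threshold(pred.scores, pred.labels)
        out = fm.group_metrics(pred, "sex")
        expected_f = fm.confusion_rates([0.3, 0.9], [1, 1], pooled_t)
        assert out["f"].tpr == expected_f.tpr

    def test_pooled_counts_equal_weighted_group_combination(self, pred_factory):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        groups = rng.choice(["f", "m", "x"], 60)
        pred = pred_factory(scores, labels, groups)
        out = fm.group_metrics(pred, "sex", threshold_policy=0.5)
        pooled = fm.confusion_rates(scores, labels, 0.5)
        tp_pooled = pooled.tpr * (labels == 1).sum()
        tp_groups = sum(out[g].tpr * out[g].n_pos for g in out)
        assert tp_pooled == pytest.approx(tp_groups)

    def test_unknown_attribute_is_an_error(self, pred_factory):
        pred = pred_factory([0.5], [1], ["f"])
        with pytest.raises(ValidationError):
            fm.group_metrics(pred, "age")

    def test_metrics_invariant_to_row_permutation(self, pred_factory):
        rng = np.random.default_rng(11)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        groups = rng.choice(["f", "m"], 40)
        perm = rng.permutation(40)
        a = pred_factory(scores, labels, groups)
        b = pred_factory(scores[perm], labels[perm], groups[perm])
        ga = fm.fairness_gap(a, "sex", ("f", "m"))
        gb = fm.fairness_gap(b, "sex", ("f", "m"))
        assert ga.signed_gap == pytest.approx(gb.signed_gap, abs=1e-12)
        assert fm.ece(a.scores, a.labels) == pytest.approx(
            fm.ece(b.scores, b.labels), abs=1e-12)


class TestFairnessGap:
    def test_signed_and_absolute_gap(self, pred_factory):
        # group f: FNR 0 (one positive, predicted); group m: FNR 1
        pred = pred_factory([0.9, 0.1, 0.8, 0.1], [1, 0, 0, 1],
                            ["f", "f", "m", "m"])
        res = fm.fairness_gap(pred, "sex", ("f", "m"), threshold_policy=0.5)
        assert res.metric == "fnr"
        assert res.signed_gap == pytest.approx(-1.0)
        assert res.absolute_gap == pytest.approx(1.0)

    def test_polarity_flag_swaps_audited_rate(self, pred_factory):
        pred = pred_factory([0.9, 0.1], [1, 0], ["f", "m"],
                            polarity="healthy_indicator")
        assert fm.fairness_gap(pred, "sex", ("f", "m"), 0.5).metric == "fpr"
        assert fm.fairness_gap(pred, "sex", ("f", "m"), 0.5,
                               overdiagnosis=True).metric == "fnr"

    def test_identical_groups_have_zero_gap(self, pred_factory):
        pred = pred_factory([0.2, 0.8, 0.2, 0.8], [0, 1, 0, 1],
                            ["f", "f", "m", "m"])
        assert fm.fairness_gap(pred, "sex", ("f", "m"), 0.5).signed_gap == 0.0


class TestGapCI:
    def test_constant_data_gives_zero_width_ci(self, pred_factory):
        pred = pred_factory([0.9, 0.9, 0.1, 0.1] * 5, [1, 1, 0, 0] * 5,
                            ["f", "m", "f", "m"] * 5)
        res = fm.gap_ci(pred, "sex", ("f", "m"), 0.5, n_boot=50, seed=1)
        assert res.ci_low == res.ci_high == 0.0
        assert res.significant is False

    def test_seeded_run_is_deterministic(self, pred_factory):
        rng = np.random.default_rng(5)
        pred = pred_factory(rng.random(100), rng.integers(0, 2, 100),
                            rng.choice(["f", "m"], 100))
        a = fm.gap_ci(pred, "sex", ("f", "m"), n_boot=100, seed=42)
        b = fm.gap_ci(pred, "sex", ("f", "m"), n_boot=100, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestRebalance:
    def test_min_cell_rule(self, pred_factory):
        # 2x2 cells sized 10,10,10,40 with one positive per 10 samples
        scores, labels, sex, age = [], [], [], []
        rng = np.random.default_rng(0)
        for g_sex, g_age, size in [("f", "y", 10), ("f", "o", 10),
                                   ("m", "y", 10), ("m", "o", 40)]:
            for i in range(size):
                scores.append(rng.random())
                labels.append(1 if i < size // 2 else 0)
                sex.append(g_sex)
                age.append(g_age)
        import pandas as pd
        from fairshift.grid_store import PredictionSet
        frame = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(scores))],
            "score": scores, "label": labels, "split": "test",
            "environment": "src", "task": "disease", "sex": sex, "age": age})
        pred = PredictionSet(frame, ("sex", "age"), "disease")
        out = fm.rebalance_eval_set(pred, ["sex", "age"], seed=0)
        cells = out.frame.groupby(["sex", "age"])
        assert set(cells.size()) == {10}
        prevalences = cells["label"].mean()
        assert len(set(prevalences.round(9))) == 1

    def test_empty_cell_is_an_error_naming_the_cell(self, pred_factory):
        pred = pred_factory([0.5, 0.6], [1, 0], ["f", "f"])
        with pytest.raises(ValidationError, match="class=1|class=0"):
            # group m absent entirely -> but single-group: class cell empty
            fm.rebalance_eval_set(pred_factory([0.5, 0.6], [1, 1], ["f", "m"]),
                                  ["sex"], seed=0)
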