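import math

import numpy as np
import pytest
from scipy.stats import norm

from fairshift import shift_stats as ss
from fairshift.grid_store import EmbeddingSet, ValidationError


class TestTvDistance:
    @pytest.mark.parametrize("p1,p2,expected", [(0.3, 0.5, 0.2), (0.4, 0.4, 0.0),
                                                (0.0, 1.0, 1.0)])
    def test_bernoulli_closed_form(self, p1, p2, expected):
        assert ss.tv_distance_binary(p1, p2) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for p1, p2 in rng.random((20, 2)):
            assert ss.tv_distance_binary(p1, p2) == ss.tv_distance_binary(p2, p1)


class TestBinomialProportionTest:
    def test_identical_proportions_give_p_one(self):
        assert ss.binomial_proportion_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_z(self):
        # pooled p = 0.7, SE = sqrt(0.7*0.3*(1/10+1/10)), z = 0.4/SE ~ 1.95
        se = math.sqrt(0.7 * 0.3 * 0.2)
        expected = 2 * (1 - norm.cdf(0.4 / se))
        p = ss.binomial_proportion_test(5, 10, 9, 10)
        assert p == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(0.051, abs=0.001)

    def test_zero_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            ss.binomial_proportion_test(0, 0, 1, 2)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(1000):
            k1, k2 = rng.binomial(200, 0.3, size=2)
            pvals.append(ss.binomial_proportion_test(k1, 200, k2, 200))
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").statistic < 0.05

    def test_fisher_variant_available(self):
        p = ss.binomial_proportion_test(1, 10, 9, 10, exact=True)
        assert 0 < p < 0.05


class TestMmd:
    def naive_mmd2(self, x1, x2, bw):
        k = lambda a, b: math.exp(-np.sum((a - b) ** 2) / (2 * bw ** 2))
        n1, n2 = len(x1), len(x2)
        t1 = sum(k(a, b) for i, a in enumerate(x1) for j, b in enumerate(x1)
                 if i != j) / (n1 * (n1 - 1))
        t2 = sum(k(a, b) for i, a in enumerate(x2) for j, b in enumerate(x2)
                 if i != j) / (n2 * (n2 - 1))
        t12 = sum(k(a, b) for a in x1 for b in x2) / (n1 * n2)
        return t1 + t2 - 2 * t12

    def test_matches_double_loop_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x1 = rng.normal(size=(rng.integers(3, 20), 3))
            x2 = rng.normal(1.0, size=(rng.integers(3, 20), 3))
            bw = 1.3
            assert ss.mmd2(x1, x2, bandwidth=bw) == pytest.approx(
                self.naive_mmd2(x1, x2, bw), abs=1e-10)

    def test_identical_samples_biased_variant_nonnegative_and_small(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4))
        assert ss.mmd2(x, x, unbiased=False) >= 0
        # the unbiased estimator on identical samples is O(1/n), not exactly 0
        assert abs(ss.mmd2(x, x)) < 5.0 / len(x)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            ss.mmd2(np.zeros((5, 2)), np.zeros((5, 3)))

    def test_separated_clouds_give_large_distance_and_rejection(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(0, 1, size=(100, 4))
        x2 = rng.normal(3, 1, size=(100, 4))
        d, p = ss.mmd_permutation_test(x1, x2, n_perm=200, seed=0)
        assert d > 0.1
        assert p == pytest.approx(1 / 201)

    def test_permutation_p_respects_add_one_floor_and_determinism(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=(30, 2))
        x2 = rng.normal(size=(30, 2))
        d1, p1 = ss.mmd_permutation_test(x1, x2, n_perm=99, seed=7)
        d2, p2 = ss.mmd_permutation_test(x1, x2, n_perm=99, seed=7)
        assert (d1, p1) == (d2, p2)
        assert p1 >= 1 / 100


class TestBonferroni:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.2], [0.02, 0.4]),
        ([0.5, 0.9], [1.0, 1.0]),
        ([0.03], [0.03]),
    ])
    def test_adjustment(self, pvals, expected):
        assert ss.bonferroni(pvals) == pytest.approx(expected)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        pvals = rng.random(10)
        for raw, adj in zip(pvals, ss.bonferroni(pvals)):
            assert adj >= raw


class TestShiftReports:
    def _embedded_pred(self, pred_factory, n, groups, rho, kappa, seed,
                       embed_y=True):
        rng = np.random.default_rng(seed)
        g = rng.choice(groups, n)
        y = (rng.random(n) < np.where(g == groups[0], rho[0], rho[1])).astype(int)
        coef = np.where(g == groups[0], -1.0, 1.0)
        x = np.column_stack([(y if embed_y else 0) + rng.normal(0, 1, n),
                             kappa * coef + rng.normal(0, 1, n)])
        pred = pred_factory(np.clip(0.5 + 0.1 * x[:, 0], 0, 1), y, g)
        emb = EmbeddingSet(pred.frame["sample_id"].to_numpy(), x)
        return pred, emb

    def test_three_groups_yield_six_tests_with_family_six(self, pred_factory):
        rng = np.random.default_rng(0)
        g = np.repeat(["a", "b", "c"], 30)
        y = rng.integers(0, 2, 90)
        pred = pred_factory(rng.random(90), y, g)
        emb = EmbeddingSet(pred.frame["sample_id"].to_numpy(),
                           rng.normal(size=(90, 2)))
        reports = ss.shift_report_id(pred, emb, "sex", n_perm=50, seed=0)
        assert len(reports) == 6
        for r in reports:
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_value))

    def test_prevalence_shift_between_groups_is_detected(self, pred_factory):
        pred, emb = self._embedded_pred(pred_factory, 500, np.array(["a", "b"]),
                                        (0.2, 0.5), 0.0, seed=1)
        reports = ss.shift_report_id(pred, emb, "sex", n_perm=100, seed=0)
        prev = [r for r in reports if r.kind == "prevalence"][0]
        assert prev.p_adjusted < 0.05
        assert prev.distance > 0.15

    def test_identical_environments_give_near_zero_distances(self, pred_factory):
        pred, emb = self._embedded_pred(pred_factory, 200, np.array(["a", "b"]),
                                        (0.3, 0.3), 0.5, seed=2)
        reports = ss.shift_report_ood(pred, pred, "sex", emb, emb,
                                      n_perm=50, seed=0)
        for r in reports:
            if r.kind in ("label", "prevalence"):
                assert r.distance == 0.0
            else:  # unbiased MMD^2 on identical samples is O(1/n)
                assert abs(r.distance) < 5.0 / r.n_1
                assert r.p_adjusted > 0.5

    def test_ood_report_length_for_two_groups(self, pred_factory):
        pred1, emb1 = self._embedded_pred(pred_factory, 150, np.array(["a", "b"]),
                                          (0.3, 0.4), 0.5, seed=3)
        pred2, emb2 = self._embedded_pred(pred_factory, 150, np.array(["a", "b"]),
                                          (0.5, 0.2), -0.5, seed=4)
        reports = ss.shift_report_ood(pred1, pred2, "sex", emb1, emb2,
                                      n_perm=50, seed=0)
        assert len(reports) == 2 + 2 * 2

    def test_prevalence_only_shift_targets_prevalence_tests(self, pred_factory):
        pred1, emb1 = self._embedded_pred(pred_factory, 600, np.array(["a", "b"]),
                                          (0.2, 0.2), 0.5, seed=5, embed_y=False)
        pred2, emb2 = self._embedded_pred(pred_factory, 600, np.array(["a", "b"]),
                                          (0.5, 0.5), 0.5, seed=6, embed_y=False)
        reports = ss.shift_report_ood(pred1, pred2, "sex", emb1, emb2,
                                      n_perm=100, seed=0)
        by_kind = {}
        for r in reports:
            by_kind.setdefault(r.kind, []).append(r)
        assert all(r.p_adjusted < 0.05 for r in by_kind["label"])
        assert all(r.p_adjusted < 0.05 for r in by_kind["prevalence"])
        assert all(r.p_adjusted > 0.05 for r in by_kind["representation"])
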