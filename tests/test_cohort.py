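"""ROC/AUC with concordance oracle, bootstrap CI, sensitivity, outliers,
group tests, and the covariate-adjusted logistic check."""

import math

import numpy as np
import pytest

from egmkit.cohort import (adjusted_logistic_check, bootstrap_auc_ci,
                           group_compare, remove_outliers, roc_auc,
                           sensitivity_leave_k_out)


def concordance_oracle(scores, labels, orientation):
    """Exhaustive pairwise concordance probability (ties count one half)."""
    s = np.asarray(scores, dtype=float)
    if orientation == "lower_is_term":
        s = -s
    term = s[np.array(labels) == "Term"]
    nonterm = s[np.array(labels) == "NonTerm"]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in term for b in nonterm)
    return wins / (term.size * nonterm.size)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], ["NonTerm"] * 3 + ["Term"] * 3,
                      "higher_is_term")
        assert res.auc == 1.0

    def test_lower_is_term_orientation(self):
        res = roc_auc([1, 2, 3, 4], ["Term", "Term", "NonTerm", "NonTerm"],
                      "lower_is_term")
        assert res.auc == 1.0

    def test_orientation_flip_maps_to_complement(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        labels = ["Term"] * 8 + ["NonTerm"] * 12
        hi = roc_auc(scores, labels, "higher_is_term").auc
        lo = roc_auc(scores, labels, "lower_is_term").auc
        assert hi + lo == pytest.approx(1.0)

    def test_matches_concordance_oracle_with_ties(self):
        """Trapezoidal ROC AUC == pairwise concordance on 50 random sets."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = ["Term" if v else "NonTerm"
                      for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                continue
            auc = roc_auc(scores, labels, "higher_is_term").auc
            assert auc == pytest.approx(
                concordance_oracle(scores, labels, "higher_is_term"))

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = ["Term" if v else "NonTerm"
                  for v in rng.integers(0, 2, 2000)]
        assert abs(roc_auc(scores, labels, "higher_is_term").auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc([1, 2], ["Term", "Term"], "higher_is_term")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            roc_auc([1.0, np.nan], ["Term", "NonTerm"], "higher_is_term")


class TestBootstrapCi:
    LABELS = ["Term"] * 6 + ["NonTerm"] * 8

    def test_perfectly_separated_ci_degenerate(self):
        scores = list(range(8, 14)) + list(range(8))
        ci = bootstrap_auc_ci(scores, self.LABELS, "higher_is_term",
                              n_boot=200, seed=0)
        assert ci == (1.0, 1.0)

    def test_single_replicate_collapses(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=14)
        lo, hi = bootstrap_auc_ci(scores, self.LABELS, "higher_is_term",
                                  n_boot=1, seed=1)
        assert lo == hi

    def test_seed_stability_at_ten_thousand_replicates(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(1.0, 1.0, 6),
                                 rng.normal(0.0, 1.0, 8)])
        a = bootstrap_auc_ci(scores, self.LABELS, "higher_is_term",
                             n_boot=10_000, seed=1)
        b = bootstrap_auc_ci(scores, self.LABELS, "higher_is_term",
                             n_boot=10_000, seed=2)
        assert abs(a[0] - b[0]) < 0.01 and abs(a[1] - b[1]) < 0.01

    def test_interior_auc_inside_ci(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0.8, 1.0, 6),
                                 rng.normal(0.0, 1.0, 8)])
        point = roc_auc(scores, self.LABELS, "higher_is_term").auc
        lo, hi = bootstrap_auc_ci(scores, self.LABELS, "higher_is_term",
                                  n_boot=2000, seed=3)
        assert lo <= point <= hi


class TestSensitivity:
    LABELS = ["Term"] * 8 + ["NonTerm"] * 10

    def test_perfect_cohort_stable(self):
        scores = list(range(20, 28)) + list(range(10))
        med, (q1, q3) = sensitivity_leave_k_out(scores, self.LABELS,
                                                "higher_is_term", k=5,
                                                n_iter=200, seed=0)
        assert med == 1.0 and q3 - q1 == 0.0

    def test_k_zero_reproduces_full_cohort(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=18)
        full = roc_auc(scores, self.LABELS, "higher_is_term").auc
        med, (q1, q3) = sensitivity_leave_k_out(scores, self.LABELS,
                                                "higher_is_term", k=0,
                                                n_iter=50, seed=0)
        assert med == q1 == q3 == pytest.approx(full)

    def test_small_removal_perturbs_mildly(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(1.5, 1.0, 8),
                                 rng.normal(0.0, 1.0, 10)])
        full = roc_auc(scores, self.LABELS, "higher_is_term").auc
        med, _ = sensitivity_leave_k_out(scores, self.LABELS,
                                         "higher_is_term", k=5,
                                         n_iter=2000, seed=1)
        assert abs(med - full) < 0.03

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_leave_k_out([1, 2, 3, 4], ["Term"] * 2 + ["NonTerm"] * 2,
                                    "higher_is_term", k=4, n_iter=10)


class TestRemoveOutliers:
    def test_gross_outlier_removed_by_iqr_rule(self):
        values = [0, 0, 0, 0, 0, 10] + [1, 2, 3, 4]
        labels = ["Term"] * 6 + ["NonTerm"] * 4
        kept, kept_lab, kept_ids, removed = remove_outliers(
            values, labels, method="iqr15")
        assert list(removed) == [5]
        assert 10 not in kept

    def test_sd3_rate_on_standard_normal(self):
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(size=1000), rng.normal(size=10)])
        labels = ["Term"] * 1000 + ["NonTerm"] * 10
        *_, removed = remove_outliers(values, labels, method="sd3")
        n_removed_term = np.sum(np.asarray(removed) < 1000)
        # expectation ~ 2 * Phi(-3) * 1000 = 2.7; binomial 99% range
        assert n_removed_term <= 10

    def test_identical_values_untouched(self):
        values = [1.0] * 5 + [2.0] * 5
        labels = ["Term"] * 5 + ["NonTerm"] * 5
        kept, *_, removed = remove_outliers(values, labels, method="auto")
        assert len(removed) == 0 and len(kept) == 10

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            remove_outliers([1, 2, 3, 1, 2, 3, 4], ["Term"] * 3 + ["NonTerm"] * 4,
                            method="sd3")


class TestGroupCompare:
    def test_identical_groups_null_p(self):
        values = list(range(10)) * 2
        labels = ["Term"] * 10 + ["NonTerm"] * 10
        _, p, _ = group_compare(values, labels, test="ranksum")
        assert p > 0.9

    def test_disjoint_groups_exact_p(self):
        """Exact rank-sum p for {1..10} vs {11..20} equals 2 / C(20, 10)."""
        values = list(range(1, 21))
        labels = ["Term"] * 10 + ["NonTerm"] * 10
        _, p, _ = group_compare(values, labels, test="ranksum")
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_shifted_normals_power(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(1.0, 1.0, 100),
                                 rng.normal(0.0, 1.0, 100)])
        labels = ["Term"] * 100 + ["NonTerm"] * 100
        for test in ("welch_t", "ranksum"):
            _, p, _ = group_compare(values, labels, test=test)
            assert p < 0.001

    def test_summary_formats(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = ["Term"] * 3 + ["NonTerm"] * 3
        _, _, s_t = group_compare(values, labels, test="welch_t")
        assert "±" in s_t["Term"]
        _, _, s_r = group_compare(values, labels, test="ranksum")
        assert "(" in s_r["Term"]


class TestAdjustedLogisticCheck:
    def _cohort(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        index = rng.normal(size=n)
        prob = 1.0 / (1.0 + np.exp(-1.5 * index))
        labels = ["Term" if rng.uniform() < p else "NonTerm" for p in prob]
        return index, labels, rng.normal(size=n)

    def test_independent_covariate_preserves_index_p(self):
        import statsmodels.api as sm
        index, labels, cov = self._cohort()
        res = adjusted_logistic_check(index, labels, cov)
        assert not res.separation
        y = np.array([1 if l == "Term" else 0 for l in labels])
        unadj = sm.Logit(y, sm.add_constant(index)).fit(disp=0)
        p_unadj = unadj.pvalues[1]
        ratio = max(res.p_value, 1e-300) / max(p_unadj, 1e-300)
        assert 0.01 < ratio < 100.0  # same order of magnitude

    def test_constant_index_uninformative(self):
        _, labels, cov = self._cohort(seed=1)
        res = adjusted_logistic_check(np.ones(len(labels)), labels, cov)
        assert not res.separation
        assert res.coef == 0.0 and res.p_value == 1.0

    def test_perfect_separation_flagged(self):
        index = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0] * 4)
        labels = (["NonTerm"] * 3 + ["Term"] * 3) * 4
        rng = np.random.default_rng(2)
        res = adjusted_logistic_check(index, labels, rng.normal(size=24))
        assert res.separation and res.p_value is None
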