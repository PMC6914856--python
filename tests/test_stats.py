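"""Statistical oracles: exact rank-sum enumeration, step-up FDR control,
Mann-Whitney/trapezoid AUC agreement, clustered variance reductions, and the
Youden operating point."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptw.stats import (auc_mann_whitney, bh_adjust, compare_groups,
                        roc_clustered, roc_curve_points, wilcoxon_rank_sum,
                        youden_operating_point)


def exact_ranksum_p(x, y):
    """Brute-force two-sided p: enumerate all assignments of ranks to group x."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    observed = ranks[:nx].sum()
    mean = nx * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: 2 of the C(6,3)=20 rank splits are as extreme."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)
        assert res.pvalue == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("x,y", [
        ([1.0, 4.0, 2.5, 7.0], [3.0, 5.5, 6.0]),
        ([10, 12], [11, 13, 14]),
    ])
    def test_exact_matches_enumeration(self, x, y):
        res = wilcoxon_rank_sum(x, y)
        assert res.pvalue == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_identical_samples_no_separation(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue > 0.9

    def test_all_values_identical(self):
        assert wilcoxon_rank_sum([5.0] * 4, [5.0] * 6).pvalue == 1.0

    def test_large_shift_significant(self, rng):
        y = rng.normal(0, 1, 20)
        res = wilcoxon_rank_sum(y + 10, y)
        assert res.pvalue < 0.001

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_published_pvalue_set_rejects_four(self):
        """BH at FDR 0.10 on the six reported raw p-values keeps exactly the
        four parameters with p <= 0.034 (mean, median, p10, p25)."""
        raw = [0.034, 0.018, 0.026, 0.024, 0.104, 0.247]
        res = bh_adjust(raw, fdr=0.10)
        assert res.rejected.sum() == 4
        assert list(res.rejected) == [True, True, True, True, False, False]

    def test_degenerate_cases(self):
        assert bh_adjust([1.0, 1.0, 1.0]).rejected.sum() == 0
        single = bh_adjust([0.04], fdr=0.10)
        assert single.adjusted[0] == pytest.approx(0.04)
        assert single.rejected[0]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_matches_bruteforce_stepup(self, pvals):
        """Adjusted p_i = min over j>=i (sorted) of m*p_(j)/j, capped at 1."""
        res = bh_adjust(pvals)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for pos in range(m - 1, -1, -1):
            running = min(running, m * p[order[pos]] / (pos + 1))
            expected[order[pos]] = running
        np.testing.assert_allclose(res.adjusted, np.minimum(expected, 1.0),
                                   atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAUC:
    def test_small_example_brute_force(self):
        """positives {0.3,0.7}, negatives {0.2,0.5}: 3 of 4 pairs ordered."""
        assert auc_mann_whitney([0.3, 0.7], [0.2, 0.5]) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=15),
           st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=15))
    def test_matches_pair_enumeration_and_flip(self, pos, neg):
        pos, neg = np.asarray(pos), np.asarray(neg)
        pairs = [(0.5 if p == n else float(p > n)) for p in pos for n in neg]
        expected = np.mean(pairs)
        assert auc_mann_whitney(pos, neg) == pytest.approx(expected, abs=1e-12)
        assert auc_mann_whitney(neg, pos) == pytest.approx(1 - expected, abs=1e-12)

    def test_equals_trapezoid_area(self, rng):
        values = np.round(rng.normal(0.6, 0.3, 120), 2)  # rounding forces ties
        labels = np.where(rng.random(120) < 0.5, "MSL", "WMH")
        if not (labels == "MSL").any() or not (labels == "WMH").any():
            pytest.skip("degenerate draw")
        curve = roc_curve_points(values, labels)
        area = -np.trapezoid(curve["tpr"], curve["fpr"])
        assert auc_mann_whitney(values[labels == "MSL"],
                                values[labels == "WMH"]) == pytest.approx(area)

    def test_perfect_separation(self):
        assert auc_mann_whitney([2.0, 3.0], [0.0, 1.0]) == 1.0


def delong_iid_variance(pos, neg):
    """Independent oracle: classic placement-value (DeLong) variance."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    m, n = pos.size, neg.size
    v10 = np.array([np.mean((neg < x) + 0.5 * (neg == x)) for x in pos])
    v01 = np.array([np.mean((pos > y) + 0.5 * (pos == y)) for y in neg])
    return np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n


class TestClusteredROC:
    def test_one_lesion_per_cluster_reduces_to_iid(self, rng):
        pos = rng.normal(0.7, 0.25, 25)
        neg = rng.normal(0.5, 0.35, 30)
        values = np.concatenate([pos, neg])
        labels = np.array(["MSL"] * 25 + ["WMH"] * 30)
        clusters = np.arange(55)
        res = roc_clustered(values, labels, clusters)
        assert res.variance == pytest.approx(delong_iid_variance(pos, neg), rel=1e-10)

    def test_duplicated_lesions_inflate_clustered_se(self, rng):
        """Perfect within-cluster duplication must widen the clustered CI
        relative to treating the duplicates as independent."""
        pos = rng.normal(0.7, 0.25, 15)
        neg = rng.normal(0.5, 0.35, 20)
        values = np.concatenate([np.repeat(pos, 2), np.repeat(neg, 2)])
        labels = np.array(["MSL"] * 30 + ["WMH"] * 40)
        clusters = np.concatenate([np.repeat(np.arange(15), 2),
                                   np.repeat(np.arange(15, 35), 2)])
        clustered = roc_clustered(values, labels, clusters)
        iid = roc_clustered(values, labels, np.arange(70))
        assert clustered.se > iid.se

    def test_mixed_class_clusters_allowed(self, rng):
        values = rng.normal(0.6, 0.3, 40)
        labels = np.array(["MSL", "WMH"] * 20)
        clusters = np.repeat(np.arange(10), 4)
        res = roc_clustered(values, labels, clusters)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_clustered(np.ones(4), np.array(["MSL"] * 4), np.arange(4))

    def test_accuracy_identity(self, rng):
        values = rng.normal(0.6, 0.3, 60)
        labels = np.where(rng.random(60) < 0.6, "MSL", "WMH")
        clusters = np.repeat(np.arange(20), 3)
        r = roc_clustered(values, labels, clusters)
        expected = (r.sensitivity * r.n_pos + r.specificity * r.n_neg) / (r.n_pos + r.n_neg)
        assert r.accuracy == pytest.approx(expected)


class TestYouden:
    def test_exhaustive_scan_example(self):
        op = youden_operating_point([0.6, 0.8, 0.2, 0.5],
                                    np.array(["MSL", "MSL", "WMH", "WMH"]))
        assert op.cutoff == pytest.approx(0.6)
        assert op.sensitivity == 1.0 and op.specificity == 1.0
        assert op.youden_j == pytest.approx(1.0)

    def test_identical_distributions_tie_break_lowest(self):
        values = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        labels = np.array(["MSL"] * 3 + ["WMH"] * 3)
        op = youden_operating_point(values, labels)
        assert op.youden_j == pytest.approx(0.0)
        assert op.cutoff == pytest.approx(0.1)   # lowest cutoff among ties

    def test_pooled_accuracy_consistency(self):
        """Operating-point accuracy at the reported class sizes: with
        sensitivity 0.434 (346 positives) and specificity 0.777 (220
        negatives), pooled accuracy is 56.7%."""
        acc = (0.434 * 346 + 0.777 * 220) / (346 + 220)
        assert acc == pytest.approx(0.567, abs=5e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20))
    def test_maximises_j_over_all_cutoffs(self, values):
        values = np.asarray(values)
        labels = np.array(["MSL", "WMH"] * (len(values) // 2)
                          + ["MSL"] * (len(values) % 2))
        if not (labels == "WMH").any():
            return
        op = youden_operating_point(values, labels)
        pos = values[labels == "MSL"]
        neg = values[labels == "WMH"]
        js = [np.mean(pos >= c) + np.mean(neg < c) - 1.0 for c in np.unique(values)]
        assert op.youden_j == pytest.approx(max(js), abs=1e-12)


class TestCompareGroups:
    @staticmethod
    def patients_frame(rng, delta=0.0, n_a=12, n_b=14):
        rows = []
        for g, n, mu in (("MSL", n_a, 0.7 + delta), ("WMH", n_b, 0.7)):
            for i in range(n):
                base = rng.normal(mu, 0.2)
                row = {"patient_id": f"{g}{i}", "group": g, "n_lesions": 5}
                for p in ("mean", "median", "p10", "p25", "p75", "p90"):
                    row[p] = base + rng.normal(0, 0.02)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self, rng):
        df = self.patients_frame(rng, delta=0.0)
        # duplicate one group into the other: literally identical values
        a = df[df.group == "MSL"].copy()
        b = a.copy()
        b["group"] = "WMH"
        b["patient_id"] = b["patient_id"] + "_b"
        out = compare_groups(pd.concat([a, b]))
        assert (out["p_raw"] > 0.9).all()
        assert not out["rejected"].any()

    def test_strong_shift_detected(self, rng):
        out = compare_groups(self.patients_frame(rng, delta=1.0))
        assert out["rejected"].all()

    def test_too_few_patients_rejected(self, rng):
        df = self.patients_frame(rng).iloc[:3]
        with pytest.raises(ValueError):
            compare_groups(df)
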