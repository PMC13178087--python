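"""Me [Q1; Q3] summaries, Mann-Whitney U, ROC AUC and cohort comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitomorph.cohort_stats import (
    compare_cohort,
    comparison_table,
    mann_whitney,
    roc_auc,
    roc_points,
    summarize,
    tukey_quartiles,
)


def brute_force_two_sided_p(g0, g1):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, with U computed
    for the first group.  Independent of any library tabulation.
    """
    pooled = np.concatenate([g0, g1])
    n0 = len(g0)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n0].sum() - n0 * (n0 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n0):
        us.append(ranks[list(idx)].sum() - n0 * (n0 + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestSummarize:
    def test_odd_n_inclusive_quartiles(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)

    def test_singleton(self):
        s = summarize([7])
        assert (s.q1, s.median, s.q3) == (7, 7, 7)

    def test_even_n(self):
        s = summarize([1, 2, 3, 4])
        assert s.median == 2.5
        assert (s.q1, s.q3) == (1.5, 3.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_monte_carlo_quartiles_match_theory(self, rng):
        x = rng.normal(10.0, 2.0, 10_000)
        q1, med, q3 = tukey_quartiles(x)
        z = 0.6744897501960817
        assert med == pytest.approx(10.0, rel=0.02)
        assert q1 == pytest.approx(10.0 - 2.0 * z, rel=0.02)
        assert q3 == pytest.approx(10.0 + 2.0 * z, rel=0.02)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n0 = int(rng.integers(2, 6))
            n1 = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n0 + n1 + 1))
            g0, g1 = pooled[:n0], pooled[n0:]
            res = mann_whitney(g0, g1, mode="exact")
            assert res.p_value == pytest.approx(brute_force_two_sided_p(g0, g1))

    def test_permutation_fallback_with_ties(self, rng):
        g0 = [1, 2, 2, 3, 4]
        g1 = [2, 4, 4, 5, 6]
        res = mann_whitney(g0, g1, mode="exact", n_permutations=20_000, seed=1)
        assert res.method == "permutation"
        oracle = brute_force_two_sided_p(np.array(g0, float), np.array(g1, float))
        assert res.p_value == pytest.approx(oracle, abs=0.02)

    def test_u_plus_u_prime(self, rng):
        for _ in range(20):
            g0 = rng.normal(size=int(rng.integers(3, 15)))
            g1 = rng.normal(size=int(rng.integers(3, 15)))
            u0 = mann_whitney(g0, g1).u_statistic
            u1 = mann_whitney(g1, g0).u_statistic
            assert u0 + u1 == pytest.approx(len(g0) * len(g1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, direction = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert direction == "higher_predicts_positive"

    def test_orientation_flag_when_lower_predicts_positive(self):
        auc, direction = roc_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert direction == "lower_predicts_positive"

    def test_null_predictor_near_half(self, rng):
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=2000)
        auc, _ = roc_auc(x, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            x = rng.integers(0, 10, size=40).astype(float)  # ties on purpose
            y = np.r_[np.zeros(25, int), np.ones(15, int)]
            rng.shuffle(y)
            raw = roc_auc_score(y, x)
            auc, direction = roc_auc(x, y)
            expected = raw if raw >= 0.5 else 1 - raw
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=60)
        y = np.r_[np.zeros(35, int), np.ones(25, int)]
        rng.shuffle(y)
        a1, d1 = roc_auc(x, y)
        a2, d2 = roc_auc(np.exp(x), y)
        assert (a1, d1) == (a2, d2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_roc_points_endpoints(self, rng):
        x = rng.normal(size=30)
        y = np.r_[np.zeros(20, int), np.ones(10, int)]
        pts = roc_points(x, y)
        assert (pts.fpr.iloc[0], pts.tpr.iloc[0]) == (0.0, 0.0)
        assert (pts.fpr.iloc[-1], pts.tpr.iloc[-1]) == (1.0, 1.0)
        assert pts.fpr.is_monotonic_increasing and pts.tpr.is_monotonic_increasing


class TestCompareCohort:
    def _frame(self, rng, shift=0.0):
        n0, n1 = 20, 12
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n0 + n1)],
                "group_label": [0] * n0 + [1] * n1,
                "taim_pct": rng.normal(45, 10, n0 + n1),
                "oimr_pct": rng.normal(31, 6, n0 + n1),
                "total_index": np.r_[
                    rng.normal(1.6, 0.5, n0), rng.normal(1.6 - shift, 0.4, n1)
                ],
            }
        )

    def test_identical_groups_auc_half_p_one(self):
        frame = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "group_label": [0, 0, 0, 0, 1, 1, 1, 1],
                "taim_pct": [40, 45, 50, 55] * 2,
                "oimr_pct": [25, 30, 35, 40] * 2,
                "total_index": [1.0, 1.2, 1.4, 1.6] * 2,
            }
        )
        comp = compare_cohort(frame)["total_index"]
        assert comp.auc == 0.5
        assert comp.p_value == pytest.approx(1.0)

    def test_detects_index_shift(self, rng):
        comp = compare_cohort(self._frame(rng, shift=0.7))["total_index"]
        assert comp.p_value <= 0.05
        assert comp.auc > 0.5
        assert comp.auc_direction == "lower_predicts_positive"

    def test_u_identity_with_auc(self, rng):
        frame = self._frame(rng, shift=0.4)
        comp = compare_cohort(frame)["total_index"]
        n0 = (frame.group_label == 0).sum()
        n1 = (frame.group_label == 1).sum()
        # U is for group 0; with "lower predicts positive" the oriented AUC
        # equals U0/(n0*n1)
        auc_raw = comp.u_statistic / (n0 * n1)
        oriented = auc_raw if comp.auc_direction == "lower_predicts_positive" else 1 - auc_raw
        assert comp.auc == pytest.approx(oriented)

    def test_missing_group_rejected(self, rng):
        frame = self._frame(rng)
        frame["group_label"] = 0
        with pytest.raises(ValueError):
            compare_cohort(frame)

    def test_table_layout(self, rng):
        table = comparison_table(compare_cohort(self._frame(rng)))
        assert list(table.parameter) == ["taim_pct", "oimr_pct", "total_index"]
        assert {"median_g0", "q1_g1", "u_statistic", "p_value", "auc"} <= set(
            table.columns
        )
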