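"""Univariate screen: U test, BH step-up, rank AUC, cut-points."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelmmc.screening import (
    bh_fdr,
    cutpoint_at_specificity,
    mann_whitney,
    marker_auc,
    screen_markers,
)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        # all 20 labelings of {10,12,14 | 1,2,3}: only U=0 and U=9 are as extreme
        u, p = mann_whitney([10, 12, 14], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1)

    def test_full_tie_symmetry(self):
        u, p = mann_whitney([5, 5], [5, 5])
        assert u == 2  # n1*n2/2
        assert p == pytest.approx(1.0)

    def test_label_swap_maps_u_and_keeps_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 10, size=6).astype(float)
            y = rng.integers(0, 10, size=8).astype(float)
            u1, p1 = mann_whitney(x, y)
            u2, p2 = mann_whitney(y, x)
            assert u1 + u2 == pytest.approx(len(x) * len(y))
            assert p1 == pytest.approx(p2)

    def test_large_sample_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x = rng.lognormal(1.0, 0.5, size=60)
        y = rng.lognormal(0.8, 0.5, size=120)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_type_one_error_calibrated_under_null(self):
        """At p < 0.05 the test rejects ~5% of null replicates."""
        rng = np.random.default_rng(12345)
        n_rep = 1000
        rejections = 0
        for _ in range(n_rep):
            x = rng.standard_normal(50)
            y = rng.standard_normal(100)
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se


class TestBhFdr:
    def test_hand_step_up_example(self):
        flags = bh_fdr([0.001, 0.01, 0.02, 0.9], q=0.05, m=4)
        # 0.02 <= 3*0.05/4 = 0.0375 pulls in the first three
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_flags_none(self):
        assert not bh_fdr([1.0] * 5, q=0.05).any()

    def test_rank_one_threshold_with_full_family(self):
        thr = 1 * 0.05 / 67
        assert bh_fdr([thr * 0.999], q=0.05, m=67)[0]
        assert not bh_fdr([thr * 1.001], q=0.05, m=67)[0]

    def test_flagged_set_is_prefix_of_sorted_order(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            flags = bh_fdr(p, q=0.1)
            order = np.argsort(p, kind="stable")
            in_order = flags[order]
            # once a False appears, no True may follow
            if in_order.any():
                last_true = np.nonzero(in_order)[0].max()
                assert in_order[: last_true + 1].all()

    def test_flags_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.random(30)
        prev = np.zeros(30, dtype=bool)
        for q in (0.01, 0.05, 0.1, 0.2, 0.5):
            cur = bh_fdr(p, q=q)
            assert (prev <= cur).all()
            prev = cur

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 50))
            ours = bh_fdr(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (ours == ref).all()

    def test_invalid_q_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5], q=1.5)


class TestAuc:
    def test_perfect_separation(self):
        assert marker_auc([10, 11], [1, 2, 3]) == 1.0

    def test_identical_groups(self):
        assert marker_auc([5, 5], [5, 5]) == 0.5

    def test_pair_enumeration_example(self):
        # wins: (3,1),(3,2),(5,1),(5,2),(5,4) -> 5 of 6
        assert marker_auc([3, 5], [1, 2, 4]) == pytest.approx(5 / 6)

    def test_rank_formula_equals_trapezoid_on_random_data(self):
        """Rank AUC equals trapezoidal ROC integration (with ties)."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(200):
            n1 = int(rng.integers(2, 30))
            n0 = int(rng.integers(2, 30))
            # integer-valued data force ties
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n0).astype(float)
            labels = np.r_[np.ones(n1), np.zeros(n0)]
            ref = roc_auc_score(labels, np.r_[x, y])
            assert marker_auc(x, y) == pytest.approx(ref, abs=1e-12)


class TestCutpoint:
    def test_counting_example(self):
        controls = np.arange(1, 21, dtype=float)
        cut, sn, sp = cutpoint_at_specificity([18, 25], controls, 95, "up")
        assert cut == 20
        assert sp == pytest.approx(95.0)
        assert sn == pytest.approx(50.0)

    def test_perfect_separation_full_sensitivity(self):
        cut, sn, sp = cutpoint_at_specificity(
            [100, 110], np.arange(1, 41, dtype=float), 95, "up"
        )
        assert sn == 100.0
        assert sp >= 95.0

    def test_down_direction_mirrors_up(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(1, 0.4, 30)
        y = rng.lognormal(0.5, 0.4, 60)
        cut_u, sn_u, sp_u = cutpoint_at_specificity(x, y, 90, "up")
        cut_d, sn_d, sp_d = cutpoint_at_specificity(-x, -y, 90, "down")
        assert cut_d == pytest.approx(-cut_u)
        assert sn_d == pytest.approx(sn_u)
        assert sp_d == pytest.approx(sp_u)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        sp=st.floats(min_value=50, max_value=99),
    )
    def test_achieved_specificity_never_below_target(self, data, sp):
        vals = st.floats(min_value=0.1, max_value=100, allow_nan=False)
        x = data.draw(st.lists(vals, min_size=1, max_size=20))
        y = data.draw(st.lists(vals, min_size=5, max_size=60))
        try:
            _, _, achieved = cutpoint_at_specificity(x, y, sp, "up")
        except ValueError:
            return  # unattainable target is allowed to refuse
        assert achieved >= sp - 1e-9

    def test_unattainable_specificity_reports_resolution(self):
        with pytest.raises(ValueError, match="minimum resolvable"):
            cutpoint_at_specificity([1.0], [5.0, 6.0, 7.0], 99, "up")


def test_screen_reports_direction_and_table_shape(default_cohort):
    cohort, _ = default_cohort
    res = screen_markers(cohort)
    frame = res.to_frame()
    assert set(frame.columns) >= {
        "marker", "p_value", "bh_significant", "auc", "cut_point",
        "sn_at_sp", "direction",
    }
    by_marker = {r.marker: r for r in res.results}
    assert by_marker["CA 19-9"].direction == "up"
    assert by_marker["PRL"].direction == "down"
    # cut-point within observed range
    for r in res.results:
        lo = min(r.case_low, r.control_low)
        hi = max(r.case_high, r.control_high)
        assert lo <= r.cut_point <= hi
    assert res.realized_p_threshold <= 0.05
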