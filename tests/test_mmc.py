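"""Scoring functions, threshold calibration and Metropolis optimization."""

from __future__ import annotations

import math

import numpy as np
import pytest

from panelmmc.cohort import BlindedCohortError, blind
from panelmmc.mmc import (
    MetropolisConfig,
    PanelModel,
    ScoringFunction,
    calibrate_threshold,
    cross_validate,
    fit_scoring_function,
    score,
    search_panels,
)
from panelmmc.screening import cutpoint_at_specificity
from panelmmc.simulate import GeneratorConfig, generate_cohort, planted_pair_specs


class TestScore:
    def test_zero_weights_score_zero(self, tiny_cohort_factory):
        cohort = tiny_cohort_factory(["a", "b"], [[2.0, 3.0]], [[1.0, 1.0]])
        sf = ScoringFunction(("a", "b"), np.zeros(2), threshold=0.0)
        assert score(sf, cohort["C0"]) == 0.0

    def test_log_identity(self, tiny_cohort_factory):
        cohort = tiny_cohort_factory(["a"], [[math.e**2]], [[1.0]])
        sf = ScoringFunction(("a",), np.array([1.0]), threshold=0.0)
        assert score(sf, cohort["C0"]) == pytest.approx(2.0)

    def test_weighted_combination(self, tiny_cohort_factory):
        cohort = tiny_cohort_factory(
            ["a", "b"], [[math.e, math.e**2]], [[1.0, 1.0]]
        )
        sf = ScoringFunction(("a", "b"), np.array([1.0, 2.0]), threshold=0.0)
        assert score(sf, cohort["C0"]) == pytest.approx(5.0)  # 1*1 + 2*2

    def test_missing_marker_named_in_error(self, tiny_cohort_factory):
        cohort = tiny_cohort_factory(["a"], [[1.0]], [[1.0]])
        sf = ScoringFunction(("a", "zz"), np.ones(2), threshold=0.0)
        with pytest.raises(KeyError, match="zz"):
            score(sf, cohort["C0"])

    def test_ranking_invariant_under_positive_scaling(self, planted_cohort):
        cohort, _ = planted_cohort
        X = cohort.marker_matrix(["MK01", "MK02"], log=True)
        w = np.array([0.7, 1.3])
        s1 = X @ w
        s2 = X @ (5.0 * w)
        assert (np.argsort(s1) == np.argsort(s2)).all()


class TestCalibrateThreshold:
    def test_target_95_on_twenty_scores(self):
        t = calibrate_threshold(np.arange(1, 21, dtype=float), 95)
        assert t == 20  # exactly one control at/above

    def test_target_50_on_twenty_scores(self):
        t = calibrate_threshold(np.arange(1, 21, dtype=float), 50)
        assert t == 11  # ten controls at/above

    def test_degenerate_all_equal_scores(self):
        scores = np.full(20, 3.0)
        t = calibrate_threshold(scores, 95)
        assert t > 3.0  # pushed just above the common value
        assert (scores >= t).sum() == 0  # SP = 100%

    def test_always_achieves_target_on_calibration_data(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(2, 80))
            # mixture of continuous and tied scores
            s = np.round(rng.standard_normal(n), rng.integers(0, 3))
            sp = float(rng.uniform(50, 99))
            t = calibrate_threshold(s, sp)
            achieved = 100.0 * (s < t).mean()
            assert achieved >= sp - 1e-9


class TestMetropolis:
    def test_incumbent_objective_is_monotone(self, planted_cohort, fast_cfg):
        cohort, _ = planted_cohort
        res = PanelModel(cohort, ("MK01", "MK02")).fit(fast_cfg)
        trace = res.objective_trace
        assert (np.diff(trace) >= 0).all()

    def test_deterministic_given_seed(self, planted_cohort, fast_cfg):
        cohort, _ = planted_cohort
        sf1 = fit_scoring_function(cohort, ("MK01", "MK02"), fast_cfg)
        sf2 = fit_scoring_function(cohort, ("MK01", "MK02"), fast_cfg)
        assert np.array_equal(sf1.coefficients, sf2.coefficients)
        assert sf1.threshold == sf2.threshold

    def test_blinded_cohort_is_refused(self, planted_cohort, fast_cfg):
        cohort, _ = planted_cohort
        blinded, _ = blind(cohort)
        with pytest.raises(BlindedCohortError):
            fit_scoring_function(blinded, ("MK01", "MK02"), fast_cfg)

    def test_single_marker_panel_recovers_univariate_rule(
        self, planted_cohort, fast_cfg
    ):
        """With one marker the optimizer cannot do materially worse than
        the univariate cut-point (the unit-weight rule is in the search
        space)."""
        cohort, _ = planted_cohort
        x, y = cohort.case_control_values("MK01")
        _, sn_uni, _ = cutpoint_at_specificity(x, y, 95, "up")
        res = PanelModel(cohort, ("MK01",)).fit(fast_cfg)
        assert res.performance.sn >= sn_uni - 1.0

    def test_two_marker_toy_matches_grid_search(self):
        """Optimized SN within 3 points of a 41x41 grid over weights."""
        rng = np.random.default_rng(10)
        n1, n0 = 200, 800
        shift = np.array([0.8, 0.8])
        Xc = rng.standard_normal((n1, 2)) + shift
        Xk = rng.standard_normal((n0, 2))
        from helpers import cohort_from_log_matrix

        cohort = cohort_from_log_matrix(["a", "b"], Xc, Xk)
        cfg = MetropolisConfig(n_iterations=400, n_splits_objective=8, seed=3)
        res = PanelModel(cohort, ("a", "b")).fit(cfg)
        # brute-force training-set SN at 95% SP over the weight grid
        X = np.vstack([Xc, Xk])
        y = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
        best = 0.0
        for w1 in np.linspace(-2, 2, 41):
            for w2 in np.linspace(-2, 2, 41):
                s = X @ np.array([w1, w2])
                t = calibrate_threshold(s[~y], 95)
                best = max(best, 100.0 * (s[y] >= t).mean())
        assert res.performance.sn >= best - 3.0

    def test_anti_informative_marker_gets_negative_weight(self):
        """A marker depressed in cases must receive a negative coefficient."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n1, n0 = 60, 120
            Xc = np.c_[rng.standard_normal(n1) + 1.0,
                       rng.standard_normal(n1) - 1.0]
            Xk = rng.standard_normal((n0, 2))
            from helpers import cohort_from_log_matrix

            cohort = cohort_from_log_matrix(["up", "down"], Xc, Xk)
            cfg = MetropolisConfig(n_splits_objective=8, seed=seed)
            sf = fit_scoring_function(cohort, ("up", "down"), cfg)
            if sf.coefficients[1] < 0:
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeds


class TestCrossValidate:
    def test_separable_toy_reaches_full_sensitivity(self):
        rng = np.random.default_rng(11)
        Xc = rng.standard_normal((30, 1)) + 10.0
        Xk = rng.standard_normal((90, 1))
        from helpers import cohort_from_log_matrix

        cohort = cohort_from_log_matrix(["m"], Xc, Xk)
        cfg = MetropolisConfig(
            n_iterations=50, n_splits_objective=4, n_cv=40, seed=2
        )
        sn, sp = cross_validate(cohort, ("m",), cfg)
        assert (sn == 100.0).all()

    def test_deterministic_given_seed(self, planted_cohort):
        cohort, _ = planted_cohort
        cfg = MetropolisConfig(
            n_iterations=30, n_splits_objective=4, n_cv=10, seed=4
        )
        sn1, sp1 = cross_validate(cohort, ("MK01", "MK03"), cfg)
        sn2, sp2 = cross_validate(cohort, ("MK01", "MK03"), cfg)
        assert np.array_equal(sn1, sn2)
        assert np.array_equal(sp1, sp2)


class TestSearchPanels:
    def test_enumerates_all_combinations(self, planted_cohort, fast_cfg):
        cohort, _ = planted_cohort
        res = search_panels(
            cohort, sizes=(2,), cfg=fast_cfg,
            markers=[f"MK{i + 1:02d}" for i in range(5)],
        )
        assert len(res.performances) == 10  # C(5,2)

    def test_three_panels_do_not_trail_two_panels(
        self, planted_cohort, fast_cfg
    ):
        cohort, _ = planted_cohort
        res = search_panels(cohort, sizes=(2, 3), cfg=fast_cfg)
        best2 = res.best(2).objective
        best3 = res.best(3).objective
        assert best3 >= best2 - 0.05  # nesting, up to CV noise

    def test_planted_pair_recovered_among_ten_markers(self):
        hits = 0
        n_seeds = 20
        cfg = MetropolisConfig(
            n_iterations=100, n_splits_objective=8, n_cv=30, seed=0
        )
        for seed in range(n_seeds):
            cohort, _ = generate_cohort(
                GeneratorConfig(
                    marker_specs=planted_pair_specs(10), seed=4000 + seed,
                    n_duplicates_case=0, n_duplicates_control=0,
                )
            )
            res = search_panels(
                cohort, sizes=(2,),
                cfg=MetropolisConfig(**{**vars(cfg), "seed": seed}),
            )
            if set(res.best(2).panel) == {"MK01", "MK02"}:
                hits += 1
        assert hits >= 0.9 * n_seeds


def test_panel_results_summary_mentions_panel(planted_cohort, fast_cfg):
    cohort, _ = planted_cohort
    res = PanelModel(cohort, ("MK01", "MK02")).fit(fast_cfg)
    text = res.summary()
    assert "MK01/MK02" in text
    assert "SP target: 95.0%" in text
    assert set(res.coefficients) == {"MK01", "MK02"}
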