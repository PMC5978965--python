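"""DVH estimation, V-metric differences, summaries, clinical-goal tables."""

import numpy as np
import pytest

from kbpkit.curation import _build_cases, _train, make_grid
from kbpkit.dvh import CumulativeDVH, dvh_from_doses_on_grid, dvh_summary
from kbpkit.simulate import CohortConfig, QualityModel, StructureSpec, generate_cohort
from kbpkit.validation import (clinical_goal_table, estimate_dvh,
                               evaluate_goal, summarize_differences,
                               v_metric_differences, validate_model)


class TestEstimateDVH:
    def test_training_case_estimate_matches_truth_noise_free(self,
                                                             noise_free_cohort,
                                                             run_cfg):
        cfg, cohort, grid = noise_free_cohort
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        cases = _build_cases(cohort[:5], "oar", cfg, grid)
        for case in cases:
            est = estimate_dvh(model, case)
            diffs = v_metric_differences(est.mean, case.total_dvh)
            assert max(abs(d) for d in diffs) <= 1.0

    def test_band_ordering_holds_for_random_queries(self, small_cohort,
                                                    run_cfg):
        cfg, cohort, grid = small_cohort
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        import dataclasses
        qcfg = dataclasses.replace(cfg, seed=999, n_plans=30)
        queries = _build_cases(generate_cohort(qcfg), "oar", qcfg, grid)
        for case in queries:
            est = estimate_dvh(model, case)
            assert np.all(est.lower.volume_fraction
                          <= est.mean.volume_fraction + 1e-12)
            assert np.all(est.mean.volume_fraction
                          <= est.upper.volume_fraction + 1e-12)
            for curve in (est.lower, est.mean, est.upper):
                assert curve.volume_fraction[0] == 1.0
                assert np.all(np.diff(curve.volume_fraction) <= 1e-12)

    def test_extrapolation_warning_for_alien_geometry(self, small_cohort,
                                                      run_cfg):
        import dataclasses
        from kbpkit.simulate import RegimeSpec
        cfg, cohort, grid = small_cohort
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        far = dataclasses.replace(cfg, seed=1000, n_plans=20,
                                  regimes=(RegimeSpec(dist_mean_mm=60.0),))
        case = _build_cases(generate_cohort(far), "oar", far, grid)[0]
        assert estimate_dvh(model, case).extrapolation_warning


class TestVMetricDifferences:
    def test_identical_curves_zero(self):
        grid = np.arange(0, 30.05, 0.05)
        dvh = dvh_from_doses_on_grid(np.linspace(1, 25, 500), grid)
        assert v_metric_differences(dvh, dvh) == (0.0, 0.0, 0.0)

    def test_uniform_offset_sign_convention(self):
        grid = np.linspace(0, 20, 2001)
        vf = np.clip(1 - grid / 40.0, 0, 1)
        clinical = CumulativeDVH(grid, vf)
        est = CumulativeDVH(grid, np.clip(vf + 0.05, 0, 1))
        d = v_metric_differences(est, clinical)
        # positive = estimate above clinical
        assert all(abs(x - 5.0) < 1e-6 for x in d)

    def test_closed_form_linear_curves(self):
        grid = np.linspace(0, 25, 2501)
        clinical = CumulativeDVH(grid, np.clip(1 - grid / 20.0, 0, 1))
        est = CumulativeDVH(grid, np.clip(1 - grid / 25.0, 0, 1))
        d_max = dvh_summary(clinical).d_max_gy  # last positive-volume edge
        expected = [100 * ((1 - f * d_max / 25) - (1 - f * d_max / 20))
                    for f in (0.50, 0.85, 0.99)]
        got = v_metric_differences(est, clinical)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=0.2)

    def test_zero_clinical_curve_rejected(self):
        # a clinical curve whose volume vanishes above 0 Gy has d_max = 0
        flat = CumulativeDVH(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        clinical = CumulativeDVH(np.array([0.0, 0.5, 1.0]),
                                 np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            v_metric_differences(flat, clinical)


class TestSummaries:
    def test_all_zero_differences(self):
        rep = summarize_differences(np.zeros((5, 3)))
        assert all(v == 0 for v in rep.mean.values())
        assert all(v == 0 for v in rep.sem.values())
        assert rep.frac_within_6 == 1.0 and rep.frac_within_10 == 1.0

    def test_plus_minus_two(self):
        rep = summarize_differences(np.array([[2.0, 2.0, 2.0],
                                              [-2.0, -2.0, -2.0]]))
        assert rep.mean["V50"] == 0.0
        assert rep.sem["V50"] == pytest.approx(2.0)

    def test_recomputation_oracle_forty_cases(self):
        rng = np.random.default_rng(60)
        D = rng.normal(1.0, 4.0, size=(40, 3))
        rep = summarize_differences(D)
        for j, m in enumerate(("V50", "V85", "V99")):
            assert rep.mean[m] == pytest.approx(D[:, j].mean())
            assert rep.sem[m] == pytest.approx(D[:, j].std(ddof=1) / np.sqrt(40))
        assert rep.frac_within_6 == pytest.approx(np.mean(np.abs(D) <= 6))
        assert rep.frac_within_6 <= rep.frac_within_10

    def test_single_case_rejected(self):
        with pytest.raises(ValueError):
            summarize_differences(np.zeros((1, 3)))

    def test_noise_free_validation_near_zero(self, noise_free_cohort, run_cfg):
        import dataclasses
        cfg, cohort, grid = noise_free_cohort
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        vcfg = dataclasses.replace(cfg, seed=777, n_plans=20)
        cases = _build_cases(generate_cohort(vcfg), "oar", vcfg, grid)
        rep = validate_model(model, cases)
        assert all(abs(v) <= 1.0 for v in rep.mean.values())


class TestClinicalGoals:
    def test_identical_pair_zero_difference(self):
        grid = np.arange(0, 30.05, 0.05)
        dvh = dvh_from_doses_on_grid(np.linspace(1, 25, 400), grid)
        table = clinical_goal_table(
            [(dvh, dvh)], [{"structure": "oar", "metric": "Dmean", "arg": None}])
        assert table[0]["mean_difference"] == 0.0

    def test_step_dvh_v5(self):
        grid = np.arange(0, 12.05, 0.05)
        step = dvh_from_doses_on_grid(np.full(50, 10.0), grid)
        assert evaluate_goal(step, "VxGy", 5.0) == pytest.approx(100.0)

    def test_unknown_metric_rejected(self):
        grid = np.array([0.0, 1.0])
        dvh = CumulativeDVH(grid, np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="unknown metric"):
            evaluate_goal(dvh, "D2cc", 2.0)

    def test_table_means_equal_column_means(self):
        rng = np.random.default_rng(61)
        grid = np.arange(0, 40.05, 0.05)
        pairs = []
        for _ in range(10):
            est = dvh_from_doses_on_grid(rng.uniform(0, 35, 300), grid)
            clin = dvh_from_doses_on_grid(rng.uniform(0, 35, 300), grid)
            pairs.append((est, clin))
        goals = [{"structure": "oar", "metric": "Dmean", "arg": None},
                 {"structure": "oar", "metric": "VxGy", "arg": 20.0}]
        table = clinical_goal_table(pairs, goals)
        for row in table:
            per_plan = [evaluate_goal(e, row["metric"], row["arg"])
                        - evaluate_goal(c, row["metric"], row["arg"])
                        for e, c in pairs]
            assert row["mean_difference"] == pytest.approx(np.mean(per_plan))
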