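"""Outlier flagging, classification, cluster detection, and the curation loop."""

import numpy as np
import pytest

from kbpkit.config import RunConfig
from kbpkit.curation import (_build_cases, _train, curate, detect_clusters,
                             flag_outliers, make_grid, modified_z_scores)
from kbpkit.regression import cooks_distance, fit_ols
from kbpkit.simulate import (CohortConfig, OutlierSpec, QualityModel,
                             RegimeSpec, StructureSpec, generate_cohort,
                             inject_outliers)


class TestModifiedZ:
    def test_constant_feature_is_silent(self):
        z = modified_z_scores(np.full(10, 3.0))
        np.testing.assert_array_equal(z, 0.0)

    def test_constant_with_one_deviant_is_infinite(self):
        z = modified_z_scores(np.array([1.0] * 9 + [5.0]))
        assert np.isinf(z[-1])

    def test_standard_normal_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        z = modified_z_scores(x)
        # for normal data the modified z approximates the ordinary z
        assert np.std(z) == pytest.approx(1.0, abs=0.05)


class TestFlagging:
    def test_clean_noise_free_cohort_has_zero_flags(self, noise_free_cohort,
                                                    run_cfg):
        cfg, cohort, grid = noise_free_cohort
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        assert flag_outliers(model, run_cfg) == []

    def test_injected_geometric_flagged_with_feature_evidence(self, run_cfg):
        cfg = CohortConfig(n_plans=40, seed=20)
        cohort = inject_outliers(generate_cohort(cfg),
                                 OutlierSpec(n_geometric=1), cfg)
        geo_id = next(p.plan_id for p in cohort
                      if p.outlier_category == "geometric")
        grid = make_grid(cfg, run_cfg)
        model = _train(cohort, "oar", cfg, run_cfg, grid)
        flags = {f.plan_id: f for f in flag_outliers(model, run_cfg)}
        assert geo_id in flags
        assert flags[geo_id].feature_robust_z > run_cfg.robust_z_threshold

    def test_single_far_pulled_case_exceeds_cooks_threshold(self):
        """One case pulled hard in y at high leverage dominates Cook's D."""
        rng = np.random.default_rng(2)
        x = np.concatenate([np.linspace(0, 1, 19), [4.0]])  # leverage point
        y = 2 * x + 0.1 * rng.standard_normal(20)
        y[-1] += 5.0  # pulled far off the line
        D = cooks_distance(fit_ols(y, x[:, None], ["x"]))
        assert D[-1] > 3.0
        assert np.all(D[:-1] < 3.0)


class TestDetectClusters:
    def test_degenerate_identical_points(self):
        k, assign = detect_clusters(np.zeros((25, 2)))
        assert k == 1 and np.all(assign == 0)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters(np.random.default_rng(0).standard_normal((10, 2)))

    def test_single_gaussian_cloud_stays_unimodal(self):
        rng = np.random.default_rng(3)
        hits = sum(detect_clusters(rng.standard_normal((40, 2)), seed=s)[0] == 1
                   for s in range(20))
        assert hits >= 19

    def test_two_separated_regimes_found_with_accurate_assignment(self):
        rng = np.random.default_rng(4)
        hits, accs = 0, []
        for s in range(20):
            a = rng.standard_normal((20, 2))
            b = rng.standard_normal((20, 2)) + np.array([6.0, 6.0])
            X = np.vstack([a, b])
            truth = np.array([0] * 20 + [1] * 20)
            k, assign = detect_clusters(X, seed=s)
            if k == 2:
                hits += 1
                accs.append(max((assign == truth).mean(),
                                (assign != truth).mean()))
        assert hits >= 19
        assert min(accs) >= 0.95

    def test_three_regimes_preferred(self):
        rng = np.random.default_rng(5)
        parts = [rng.standard_normal((15, 2)) + off
                 for off in ([0, 0], [7, 0], [3.5, 7])]
        k, _ = detect_clusters(np.vstack(parts), seed=0)
        assert k == 3


class TestCurate:
    def test_clean_cohort_no_actions_single_iteration(self, noise_free_cohort,
                                                      run_cfg):
        cfg, cohort, grid = noise_free_cohort
        model, log = curate(cohort, "oar", cfg, run_cfg,
                            _skip_cluster_check=True)
        assert len(log.iterations) == 1
        assert log.all_actions == []

    def test_curate_is_deterministic(self, run_cfg):
        cfg = CohortConfig(n_plans=40, seed=21)
        cohort = inject_outliers(generate_cohort(cfg),
                                 OutlierSpec(n_dosimetric=2, n_geometric=1), cfg)
        out = []
        for _ in range(2):
            model, log = curate(cohort, "oar", cfg, run_cfg,
                                _skip_cluster_check=True)
            out.append([(a.plan_id, a.action, a.category)
                        for it in log.iterations for a in it.actions])
        assert out[0] == out[1]

    def test_end_to_end_recovery_on_one_seed(self, run_cfg):
        cfg = CohortConfig(n_plans=40, seed=1001)
        cohort = inject_outliers(
            generate_cohort(cfg),
            OutlierSpec(n_dosimetric=4, dq_shift=3.0, n_geometric=1,
                        n_overfitting=1), cfg)
        cats = {p.plan_id: p.outlier_category for p in cohort}
        model, log = curate(cohort, "oar", cfg, run_cfg,
                            _skip_cluster_check=True)
        acted = {a.plan_id: a for a in log.all_actions}
        replaced = [pid for pid, a in acted.items()
                    if a.action == "replace_with_replan"]
        removed = [pid for pid, a in acted.items()
                   if a.action == "remove_structure"]
        assert sum(cats[pid] == "dosimetric" for pid in replaced) >= 3
        assert any(cats[pid] == "geometric" for pid in removed)
        assert any(cats[pid] == "overfitting" for pid in removed)

    def test_influence_removal_shrinks_max_cooks(self, run_cfg):
        cfg = CohortConfig(n_plans=40, seed=22)
        cohort = inject_outliers(generate_cohort(cfg),
                                 OutlierSpec(n_geometric=1), cfg)
        geo_id = next(p.plan_id for p in cohort
                      if p.outlier_category == "geometric")
        grid = make_grid(cfg, run_cfg)
        before = _train(cohort, "oar", cfg, run_cfg, grid)
        after = _train([p for p in cohort if p.plan_id != geo_id], "oar",
                       cfg, run_cfg, grid)
        assert after.diagnostics.max_cooks.max() \
            < before.diagnostics.max_cooks.max()

    def test_cluster_split_policy(self, run_cfg):
        two = (RegimeSpec(weight=0.5, dist_mean_mm=22.0),
               RegimeSpec(weight=0.5, dist_mean_mm=40.0))
        cfg = CohortConfig(n_plans=60, seed=23, regimes=two)
        cohort = generate_cohort(cfg)
        result, log = curate(cohort, "oar", cfg, run_cfg)
        assert log.cluster_k == 2
        assert isinstance(result, dict) and len(result) == 2

    def test_cluster_merge_policy_warns(self, run_cfg):
        import dataclasses
        two = (RegimeSpec(weight=0.5, dist_mean_mm=22.0),
               RegimeSpec(weight=0.5, dist_mean_mm=40.0))
        cfg = CohortConfig(n_plans=48, seed=23, regimes=two)
        merge_cfg = dataclasses.replace(run_cfg, cluster_policy="merge")
        result, log = curate(generate_cohort(cfg), "oar", cfg, merge_cfg)
        assert log.cluster_k == 2
        assert not isinstance(result, dict)
        assert any("merged" in w for w in log.warnings)

    def test_non_influential_geometric_kept(self, run_cfg):
        """The paper's rule: geometry alone does not remove a plan."""
        import dataclasses
        # a mild geometric deviation: higher overlap than anyone, but not
        # enough leverage to dominate the regression
        cfg = CohortConfig(n_plans=40, seed=25)
        spec = OutlierSpec(n_geometric=1, overlap_range=(0.12, 0.15),
                           geometric_spread_factor=1.0)
        cohort = inject_outliers(generate_cohort(cfg), spec, cfg)
        geo_id = next(p.plan_id for p in cohort
                      if p.outlier_category == "geometric")
        model, log = curate(cohort, "oar", cfg, run_cfg,
                            _skip_cluster_check=True)
        removed = [a.plan_id for a in log.all_actions
                   if a.action == "remove_structure"]
        flags = [f for it in log.iterations for f in it.flags
                 if f.plan_id == geo_id]
        if flags and not any(f.influential for f in flags):
            assert geo_id not in removed
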