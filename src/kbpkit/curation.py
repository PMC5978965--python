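"""Outlier curation: flag, classify, act, iterate.

The commissioning loop mirrors clinical model curation practice:

1. train the model and inspect diagnostics;
2. flag potential outliers — influential cases (Cook's distance above 3),
   gross residual outliers (|studentized residual| above 3), feature-space
   outliers (modified z above 3.5), and "scatter" candidates beyond the
   2-SD band of the regression scatter plots;
3. classify each candidate by *trial re-planning*: if a fresh plan with
   population-typical quality lowers the mean OAR dose by more than the
   re-plan margin, the case is a **dosimetric** outlier and is replaced by
   its re-plan; otherwise, if its geometry features are population-extreme
   or its leverage is high, it is **geometric** (removed only when
   influential — non-influential geometric cases carry useful information
   and stay); otherwise a remove-and-refit trial checks whether dropping
   the case shrinks the model (fewer retained components/terms or a clear
   chi-squared drop) — if so it is an **over-fitting** case and is removed;
4. act on at most ``batch`` strongest candidates per iteration, retrain,
   and stop once no further significant improvement is seen.

A Gaussian-mixture cluster check runs before the loop: bipolar or tripolar
score clouds (distinct treatment-technique regimes) are better served by
separate models, so the cohort is split (or deliberately merged, per
policy) before curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .simulate import CohortConfig, SyntheticPlan, mean_oar_dose, replan
from .training import (StructureModel, TrainingCase, case_from_voxels,
                       project_scores, reconstruct, train_structure_model)

MAX_CLUSTERS = 3


# ---------------------------------------------------------------------------
# Flags and actions
# ---------------------------------------------------------------------------

@dataclass
class OutlierFlag:
    plan_id: str
    structure: str
    cooks_distance: float
    studentized_residual: float
    leverage: float
    feature_robust_z: float
    influential: bool
    reasons: list = field(default_factory=list)  # subset of
    # {"influential", "residual", "feature", "scatter"}


@dataclass
class CurationAction:
    plan_id: str
    structure: str
    action: str     # remove_structure | replace_with_replan | keep
    category: str   # geometric | dosimetric | overfitting | none
    rationale: str
    evidence: dict = field(default_factory=dict)


@dataclass
class CurationIteration:
    iteration: int
    n_cases: int
    r_squared: float
    chi_squared: float
    max_cooks: float
    n_flags: int
    flags: list = field(default_factory=list)
    actions: list = field(default_factory=list)


@dataclass
class CurationLog:
    structure: str
    iterations: list = field(default_factory=list)
    cluster_k: int = 1
    cluster_policy: str = "split"
    warnings: list = field(default_factory=list)

    @property
    def all_actions(self) -> list:
        return [a for it in self.iterations for a in it.actions
                if a.action != "keep"]


def modified_z_scores(values: np.ndarray) -> np.ndarray:
    """Modified z via median/MAD: 0.6745 (x - med) / MAD.

    A zero MAD (constant feature) yields z = 0 everywhere except genuinely
    deviating points, which are reported as infinite.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        out = np.zeros(x.size)
        out[np.abs(x - med) > 1e-12] = np.inf
        return out
    return 0.6745 * (x - med) / mad


def flag_outliers(model: StructureModel, cfg: RunConfig) -> list[OutlierFlag]:
    """All outlier candidates of a trained model.

    Hard flags: Cook's D > threshold (influential), |studentized residual|
    > threshold, feature modified z > threshold.  Soft "scatter" candidates
    sit beyond the ``scatter_sd`` band of the regression scatter plots and
    are examined by the classification trials, mirroring the visual
    potential-outlier screen of commissioning practice.
    """
    diag = model.diagnostics
    F = model.predictor_matrix[:, model.ged_basis.n_components:]
    robust_z = np.zeros((len(diag.case_ids), F.shape[1]))
    for j in range(F.shape[1]):
        robust_z[:, j] = modified_z_scores(F[:, j])
    max_z = np.abs(robust_z).max(axis=1) if F.shape[1] else np.zeros(len(diag.case_ids))

    # studentized residuals and Cook's D are scale-free; on a numerically
    # exact fit (1 - R^2 below ~1e-3) they resolve discretization noise,
    # not model departures, so those PCs cannot generate flags
    if diag.per_pc_r_squared:
        informative = np.array([1.0 - r2 > 1e-3 for r2 in diag.per_pc_r_squared])
    else:  # e.g. a reloaded model without per-PC diagnostics
        informative = np.ones(diag.cooks.shape[1], dtype=bool)
    cooks = np.where(informative[None, :], diag.cooks, 0.0).max(axis=1)
    stud = np.abs(np.where(informative[None, :], diag.studentized, 0.0)).max(axis=1)

    flags = []
    for i, pid in enumerate(diag.case_ids):
        D = float(cooks[i])
        t = float(stud[i])
        z = float(max_z[i])
        reasons = []
        if D > cfg.cooks_threshold:
            reasons.append("influential")
        if t > cfg.residual_threshold:
            reasons.append("residual")
        if z > cfg.robust_z_threshold:
            reasons.append("feature")
        if not reasons and t > cfg.scatter_sd:
            reasons.append("scatter")
        if reasons:
            flags.append(OutlierFlag(
                plan_id=pid, structure=model.structure, cooks_distance=D,
                studentized_residual=t, leverage=float(diag.max_leverage[i]),
                feature_robust_z=z, influential=D > cfg.cooks_threshold,
                reasons=reasons))
    return flags


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def replan_dose_drop(plan: SyntheticPlan, cohort_cfg: CohortConfig,
                     structure: str, n_draws: int = 5) -> tuple[float, float]:
    """Trial re-planning: (median mean-dose drop, SD of the re-plan doses).

    The SD over the trial re-plans measures how much planner-to-planner
    variation this particular geometry admits, so the drop can be judged
    on a per-patient scale with no geometric variance mixed in.
    """
    base = mean_oar_dose(plan, structure)
    doses = [mean_oar_dose(replan(plan, cohort_cfg, draw=d), structure)
             for d in range(n_draws)]
    drop = base - float(np.median(doses))
    return drop, float(np.std(doses, ddof=1))


def cohort_replan_scale(plans: list[SyntheticPlan], cohort_cfg: CohortConfig,
                        structure: str, cfg: RunConfig) -> float:
    """Typical planner-to-planner mean-dose SD across the cohort.

    Estimated once per curation run by trial re-planning a deterministic
    sample of plans and pooling the within-plan deviations.  Re-plan draws
    always come from the unshifted quality population, so outlier plans in
    the sample cannot distort the scale.
    """
    n = min(cfg.n_scale_plans, len(plans))
    idx = np.linspace(0, len(plans) - 1, n).astype(int)
    ss, df = 0.0, 0
    for i in idx:
        doses = np.array([mean_oar_dose(replan(plans[i], cohort_cfg, draw=d),
                                        structure)
                          for d in range(cfg.n_scale_draws)])
        ss += float(np.sum((doses - doses.mean()) ** 2))
        df += doses.size - 1
    return float(np.sqrt(ss / df))


def classify_outlier(flag: OutlierFlag, plan: SyntheticPlan,
                     model: StructureModel, cohort_cfg: CohortConfig,
                     cfg: RunConfig, retrain_without,
                     case: TrainingCase | None = None,
                     replan_scale: float | None = None) -> CurationAction:
    """Decide what a flagged case is and what to do about it.

    ``retrain_without`` is a callable (plan_id) -> StructureModel used by
    the remove-and-refit over-fitting trial.
    """
    structure = flag.structure
    drop, replan_sd = replan_dose_drop(plan, cohort_cfg, structure,
                                       cfg.n_replan_draws)
    if replan_scale is None:
        scale = replan_sd
    else:
        # per-plan scale shrunk toward the cohort scale: tracks how much
        # planner variation this geometry admits without the noise of a
        # small per-plan draw set
        scale = float(np.sqrt(0.5 * replan_sd ** 2 + 0.5 * replan_scale ** 2))
    margin = cfg.replan_margin_sd * max(scale, 1e-9)
    evidence = {"replan_drop_gy": drop, "replan_margin_gy": margin,
                "cooks_distance": flag.cooks_distance,
                "studentized_residual": flag.studentized_residual,
                "feature_robust_z": flag.feature_robust_z,
                "leverage": flag.leverage}
    if drop > margin:
        return CurationAction(
            plan_id=flag.plan_id, structure=structure,
            action="replace_with_replan", category="dosimetric",
            rationale=f"trial re-plan reduced mean dose by {drop:.2f} Gy "
                      f"(> {margin:.2f} Gy margin)", evidence=evidence)

    n, p = model.pc_fits[0].n, max(f.p for f in model.pc_fits)
    if flag.feature_robust_z > cfg.robust_z_threshold or flag.leverage > 3.0 * p / n:
        action = "remove_structure" if flag.influential else "keep"
        why = ("influential (Cook's D "
               f"{flag.cooks_distance:.1f} > {cfg.cooks_threshold}); removed"
               if flag.influential else
               "non-influential; kept — may inform similar future geometries")
        return CurationAction(plan_id=flag.plan_id, structure=structure,
                              action=action, category="geometric",
                              rationale=f"geometry outside the population; {why}",
                              evidence=evidence)

    trial = retrain_without(flag.plan_id)
    if trial is not None and case is not None and case.in_field_part is not None:
        # Remove-and-refit: does the remaining cohort's component space still
        # represent this curve?  If not, the case alone forced an extra
        # variance direction into the model — the over-fitting signature.
        y = case.in_field_part.volume_fraction
        recon = reconstruct(trial.dvh_basis, project_scores(trial.dvh_basis, y))
        err = float(np.sqrt(np.mean((y - recon) ** 2)))
        k = trial.dvh_basis.n_components
        discarded = float(trial.dvh_basis.eigenvalues[k:].sum())
        typical = float(np.sqrt(max(discarded, 0.0) / y.size))
        evidence["complexity_before"] = model.complexity
        evidence["complexity_after"] = trial.complexity
        evidence["loo_recon_rms"] = err
        evidence["typical_recon_rms"] = typical
        if err > cfg.overfit_recon_floor and \
                err > cfg.overfit_recon_ratio * max(typical, 1e-12):
            return CurationAction(
                plan_id=flag.plan_id, structure=structure,
                action="remove_structure", category="overfitting",
                rationale="curve unrepresentable without its own component "
                          f"(leave-out RMS {err:.4f} vs typical {typical:.4f})",
                evidence=evidence)
    return CurationAction(plan_id=flag.plan_id, structure=structure,
                          action="keep", category="none",
                          rationale="re-plan cannot reduce the dose, geometry "
                                    "typical, removal does not shrink the model",
                          evidence=evidence)


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(scores: np.ndarray, seed: int = 0,
                    bic_margin: float = 20.0) -> tuple[int, np.ndarray]:
    """Choose k in {1, 2, 3} Gaussian-mixture components on score pairs.

    A larger k is preferred only when it beats the best smaller k by
    ``bic_margin`` BIC points, so unimodal clouds stay k = 1.
    """
    from sklearn.mixture import GaussianMixture

    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 20:
        raise ValueError("need at least 20 cases for cluster detection")
    if np.allclose(X, X[0], atol=1e-12):
        return 1, np.zeros(X.shape[0], dtype=int)
    fits, bics = {}, {}
    for k in range(1, MAX_CLUSTERS + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=5, random_state=seed, reg_covar=1e-6)
        gm.fit(X)
        fits[k], bics[k] = gm, gm.bic(X)
    best = 1
    for k in range(2, MAX_CLUSTERS + 1):
        if bics[k] < bics[best] - bic_margin:
            best = k
    return best, fits[best].predict(X)


# ---------------------------------------------------------------------------
# The curation loop
# ---------------------------------------------------------------------------

def _build_cases(plans: list[SyntheticPlan], structure: str,
                 cohort_cfg: CohortConfig, grid: np.ndarray) -> list[TrainingCase]:
    cases = []
    for p in plans:
        ss = p.structures[structure]
        cases.append(case_from_voxels(p.plan_id, structure, ss.geometry(cohort_cfg),
                                      ss.achieved_dose_gy, grid,
                                      cohort_cfg.falloff_sigma_mm,
                                      cohort_cfg.thresholds))
    return cases


def make_grid(cohort_cfg: CohortConfig, cfg: RunConfig) -> np.ndarray:
    n = int(np.ceil(cfg.grid_max_factor * cohort_cfg.rx_gy / cfg.bin_width_gy)) + 1
    return np.arange(n, dtype=float) * cfg.bin_width_gy


def _train(plans, structure, cohort_cfg, cfg, grid) -> StructureModel:
    return train_structure_model(
        _build_cases(plans, structure, cohort_cfg, grid), grid,
        variance_threshold=cfg.variance_threshold,
        ged_variance_threshold=cfg.ged_variance_threshold,
        alpha_in=cfg.alpha_in, allow_interactions=cfg.allow_interactions,
        min_cases=cfg.min_plans, warn=False)


def _train_with_cases(plans, structure, cohort_cfg, cfg, grid):
    cases = _build_cases(plans, structure, cohort_cfg, grid)
    model = train_structure_model(
        cases, grid, variance_threshold=cfg.variance_threshold,
        ged_variance_threshold=cfg.ged_variance_threshold,
        alpha_in=cfg.alpha_in, allow_interactions=cfg.allow_interactions,
        min_cases=cfg.min_plans, warn=False)
    return model, {c.plan_id: c for c in cases}


def curate(plans: list[SyntheticPlan], structure: str,
           cohort_cfg: CohortConfig, cfg: RunConfig,
           _skip_cluster_check: bool = False):
    """Run the full iterative curation loop for one structure.

    Returns ``(model, log)`` — or, when the cluster check finds k > 1 under
    the "split" policy, ``(dict cluster_id -> (model, log), log)`` with the
    top-level log recording the split.
    """
    grid = make_grid(cohort_cfg, cfg)
    log = CurationLog(structure=structure, cluster_policy=cfg.cluster_policy)
    model, case_map = _train_with_cases(plans, structure, cohort_cfg, cfg, grid)

    if not _skip_cluster_check and len(plans) >= 20:
        pairs = np.column_stack([model.predictor_matrix[:, 0],
                                 model.dvh_scores[:, 0]])
        k, assign = detect_clusters(pairs, seed=cfg.seed,
                                    bic_margin=cfg.cluster_bic_margin)
        log.cluster_k = k
        if k > 1:
            if cfg.cluster_policy == "split":
                groups = {}
                id_to_cluster = dict(zip(model.case_ids, assign))
                for p in plans:
                    groups.setdefault(int(id_to_cluster.get(p.plan_id, 0)), []).append(p)
                small = [c for c, g in groups.items() if len(g) < cfg.min_plans]
                if small:
                    log.warnings.append(
                        f"{k} clusters detected but {len(small)} below the "
                        f"{cfg.min_plans}-plan floor; merged instead")
                else:
                    results = {}
                    for c, group in sorted(groups.items()):
                        results[c] = curate(group, structure, cohort_cfg, cfg,
                                            _skip_cluster_check=True)
                    log.warnings.append(f"split into {k} cluster models")
                    return results, log
            else:
                log.warnings.append(
                    f"{k} clusters detected; merged per policy — expect a "
                    "widened estimate band")

    current = list(plans)
    cleared: set = set()
    prev_r2 = prev_chi2 = None
    replan_scale = cohort_replan_scale(plans, cohort_cfg, structure, cfg)
    for it in range(1, cfg.max_iter + 1):
        diag = model.diagnostics
        flags = flag_outliers(model, cfg)
        # a "keep" verdict clears soft scatter candidates for good; cases
        # with hard statistical flags stay eligible for re-examination
        candidates = [f for f in flags
                      if set(f.reasons) != {"scatter"} or f.plan_id not in cleared]
        record = CurationIteration(
            iteration=it, n_cases=len(model.case_ids),
            r_squared=diag.r_squared, chi_squared=diag.chi_squared,
            max_cooks=float(diag.max_cooks.max()), n_flags=len(flags),
            flags=flags)
        log.iterations.append(record)
        if not candidates:
            break
        hard_left = any(set(f.reasons) != {"scatter"} for f in candidates)
        if prev_r2 is not None and not hard_left \
                and abs(diag.r_squared - prev_r2) < cfg.stop_delta_r2 \
                and abs(diag.chi_squared - prev_chi2) < cfg.stop_delta_chi2 \
                and diag.chi_squared <= cfg.chi_squared_threshold:
            break  # no significant improvement and nothing gross left
        candidates.sort(key=lambda f: (f.cooks_distance,
                                       abs(f.studentized_residual)),
                        reverse=True)
        by_id = {p.plan_id: p for p in current}

        def retrain_without(pid):
            rest = [p for p in current if p.plan_id != pid]
            if len(rest) < 2:
                return None
            return _train(rest, structure, cohort_cfg, cfg, grid)

        n_actions = 0
        for f in candidates:
            if n_actions >= cfg.batch:
                break
            if f.plan_id not in by_id:
                continue
            act = classify_outlier(f, by_id[f.plan_id], model, cohort_cfg, cfg,
                                   retrain_without, case=case_map.get(f.plan_id),
                                   replan_scale=replan_scale)
            record.actions.append(act)
            if act.action == "replace_with_replan":
                # the accepted re-plan comes from a draw block disjoint from
                # the trial draws, so repeated replacement is a fresh plan
                current = [replan(p, cohort_cfg, draw=1000 + p.replan_count)
                           if p.plan_id == act.plan_id else p
                           for p in current]
                n_actions += 1
            elif act.action == "remove_structure":
                current = [p for p in current if p.plan_id != act.plan_id]
                n_actions += 1
            else:
                cleared.add(f.plan_id)
        if n_actions == 0:
            break
        if len(current) < cfg.min_plans:
            log.warnings.append(f"cohort fell below the {cfg.min_plans}-plan floor")
        prev_r2, prev_chi2 = diag.r_squared, diag.chi_squared
        model, case_map = _train_with_cases(current, structure, cohort_cfg, cfg, grid)
    else:
        log.warnings.append("max_iter reached before convergence; "
                            "returning best-so-far model")
    return model, log
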