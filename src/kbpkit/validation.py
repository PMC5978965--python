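"""DVH estimation for new geometries and max-dose-normalized validation.

An estimate combines the four region parts by volume weight:

* in-field: PCA mean plus predicted principal-component scores (from the
  trained regressions) times the eigenvectors;
* overlap: the overlap model's mean curve;
* leaf-transmission: a step at the transmission dose level;
* out-of-field: a step at 0 Gy.

The band around the mean curve propagates each PC's prediction standard
error through its eigenvector (plus the overlap SD curve), then repairs
monotonicity with a left-to-right running minimum and clamps to [0, 1].

Validation follows commissioning practice: estimated and clinical curves
are compared at 50%, 85% and 99% of the *clinical* maximum OAR dose
(denoted V50, V85, V99), differences reported in percent volume with the
convention positive = estimate above clinical, summarized as mean ± SEM
plus the fractions of cases within 6% and 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh import CumulativeDVH, dvh_summary, volume_at_dose
from .training import StructureModel, TrainingCase, project_scores, reconstruct
from .regression import prediction_se

V_METRIC_FRACTIONS = (0.50, 0.85, 0.99)
V_METRIC_NAMES = ("V50", "V85", "V99")


@dataclass
class DVHEstimate:
    mean: CumulativeDVH
    lower: CumulativeDVH
    upper: CumulativeDVH
    band_z: float
    extrapolation_warning: bool = False
    predicted_scores: np.ndarray | None = None


def _as_dvh(grid: np.ndarray, vf: np.ndarray) -> CumulativeDVH:
    vf = np.clip(vf, 0.0, 1.0)
    vf = np.minimum.accumulate(vf)  # running minimum repairs monotonicity
    vf[0] = 1.0
    return CumulativeDVH(grid, vf)


def _step_curve(grid: np.ndarray, level_gy: float) -> np.ndarray:
    return (grid <= level_gy).astype(float)


def estimate_dvh(model: StructureModel, case: TrainingCase,
                 band_z: float = 1.0) -> DVHEstimate:
    """Estimate the full-structure DVH (with band) for one geometry.

    ``case`` needs the GED histogram, scalar features and region fractions;
    its dose data (if any) are not consulted.
    """
    grid = model.grid
    x = model.predictor_row(case)

    # in-field part: predicted PCS -> reconstruction; SE per PC
    name_to_col = {nm: j for j, nm in enumerate(model.predictor_names)}
    scores = np.zeros(model.dvh_basis.n_components)
    ses = np.zeros(model.dvh_basis.n_components)
    for k, fit in enumerate(model.pc_fits):
        row = np.array([x[name_to_col[t]] for t in fit.terms])
        scores[k] = fit.coef[0] + row @ fit.coef[1:]
        ses[k] = prediction_se(fit, row)
    infield_mean = reconstruct(model.dvh_basis, scores)
    V = model.dvh_basis.eigenvectors[: model.dvh_basis.n_components]
    infield_hw = band_z * np.sqrt((ses[:, None] ** 2 * V ** 2).sum(axis=0))

    fr = case.region_fractions
    parts_mean = fr["in_field"] * infield_mean
    halfwidth = fr["in_field"] * infield_hw
    if fr["overlap"] > 0:
        if model.overlap_model is not None:
            parts_mean = parts_mean + fr["overlap"] * model.overlap_model.mean_curve
            halfwidth = halfwidth + band_z * fr["overlap"] * model.overlap_model.sd_curve
        else:
            parts_mean = parts_mean + fr["overlap"] * _step_curve(grid, model.rx_gy)
    parts_mean = parts_mean + fr["leaf_transmission"] * _step_curve(
        grid, model.transmission_dose_gy)
    parts_mean = parts_mean + fr["out_of_field"] * _step_curve(grid, 0.0)

    # extrapolation check against the training hull
    lo = model.predictor_matrix.min(axis=0)
    hi = model.predictor_matrix.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    outside = bool(np.any((x < lo - 0.05 * span) | (x > hi + 0.05 * span)))

    return DVHEstimate(
        mean=_as_dvh(grid, parts_mean),
        lower=_as_dvh(grid, parts_mean - halfwidth),
        upper=_as_dvh(grid, parts_mean + halfwidth),
        band_z=band_z, extrapolation_warning=outside,
        predicted_scores=scores)


def v_metric_differences(estimated: CumulativeDVH,
                         clinical: CumulativeDVH) -> tuple[float, float, float]:
    """(dV50, dV85, dV99) in percent volume at fractions of clinical d_max.

    Sign convention: positive means the estimated DVH lies above the
    clinical one (the model predicts more irradiated volume than achieved).
    """
    d_max = dvh_summary(clinical).d_max_gy
    if d_max <= 0:
        raise ValueError("clinical curve is identically zero")
    out = []
    for frac in V_METRIC_FRACTIONS:
        d = frac * d_max
        out.append(100.0 * (volume_at_dose(estimated, d) - volume_at_dose(clinical, d)))
    return tuple(out)


@dataclass
class ValidationReport:
    structure: str
    n: int
    mean: dict            # metric -> mean difference (% volume)
    sem: dict             # metric -> standard error of the mean
    frac_within_6: float  # over all case x metric entries
    frac_within_10: float
    differences: np.ndarray = field(repr=False)  # (n, 3)

    def as_dict(self) -> dict:
        return {
            "structure": self.structure, "n": self.n,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sem": {k: float(v) for k, v in self.sem.items()},
            "frac_within_6": float(self.frac_within_6),
            "frac_within_10": float(self.frac_within_10),
        }


def summarize_differences(differences: np.ndarray,
                          structure: str = "") -> ValidationReport:
    """Mean +/- SEM per metric and within-6%/10% fractions."""
    D = np.atleast_2d(np.asarray(differences, dtype=float))
    if D.shape[0] < 2:
        raise ValueError("need at least 2 validation cases")
    mean = {m: float(D[:, j].mean()) for j, m in enumerate(V_METRIC_NAMES)}
    sem = {m: float(D[:, j].std(ddof=1) / np.sqrt(D.shape[0]))
           for j, m in enumerate(V_METRIC_NAMES)}
    absd = np.abs(D)
    return ValidationReport(
        structure=structure, n=D.shape[0], mean=mean, sem=sem,
        frac_within_6=float((absd <= 6.0).mean()),
        frac_within_10=float((absd <= 10.0).mean()),
        differences=D)


def validate_model(model: StructureModel, cases: list[TrainingCase],
                   band_z: float = 1.0) -> ValidationReport:
    """Estimate every validation case and summarize V-metric differences."""
    rows = []
    for c in cases:
        est = estimate_dvh(model, c, band_z=band_z)
        rows.append(v_metric_differences(est.mean, c.total_dvh))
    return summarize_differences(np.array(rows), structure=model.structure)


# ---------------------------------------------------------------------------
# Clinical-goal tables
# ---------------------------------------------------------------------------

def evaluate_goal(dvh: CumulativeDVH, metric: str, arg: float | None = None,
                  voxel_volume_scale: float = 1.0) -> float:
    """Evaluate one clinical-goal metric on a curve.

    ``metric``: "VxGy" (volume % at ``arg`` Gy), "DxPct" (dose at ``arg`` %
    volume), "Dmean" or "Dmax".
    """
    if metric == "VxGy":
        return 100.0 * volume_at_dose(dvh, float(arg))
    if metric == "DxPct":
        from .dvh import dose_at_volume
        return dose_at_volume(dvh, float(arg) / 100.0)
    s = dvh_summary(dvh)
    if metric == "Dmean":
        return s.d_mean_gy
    if metric == "Dmax":
        return s.d_max_gy
    raise ValueError(f"unknown metric type {metric!r}")


def clinical_goal_table(pairs: list[tuple[CumulativeDVH, CumulativeDVH]],
                        goals: list[dict]) -> list[dict]:
    """Per-goal model-vs-clinical differences with mean and SD.

    ``goals``: list of {"structure", "metric", "arg"} dicts; ``pairs`` are
    (estimated, clinical) curves for one structure each.
    """
    out = []
    for goal in goals:
        diffs, est_vals, clin_vals = [], [], []
        for est, clin in pairs:
            e = evaluate_goal(est, goal["metric"], goal.get("arg"))
            c = evaluate_goal(clin, goal["metric"], goal.get("arg"))
            est_vals.append(e)
            clin_vals.append(c)
            diffs.append(e - c)
        diffs = np.array(diffs)
        out.append({
            **goal,
            "mean_estimated": float(np.mean(est_vals)),
            "mean_clinical": float(np.mean(clin_vals)),
            "mean_difference": float(diffs.mean()),
            "sd_difference": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        })
    return out
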