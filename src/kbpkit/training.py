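"""DVH-estimation model training.

Per structure, the model has four parts mirroring the four-region OAR
decomposition:

* **overlap** — mean and SD curves of the overlap-region DVH parts (the
  target dominates there, so the shapes are similar across plans);
* **in-field** — the interesting region: the in-field DVH parts are
  compressed by PCA into principal-component scores (PCS), and each
  retained PCS is regressed by forward stepwise selection on the GED
  histogram PCS plus the four scalar geometry features;
* **leaf-transmission** — a fixed step at the transmission dose level;
* **out-of-field** — a step at 0 Gy.

Diagnostics (pooled R-squared, parameter-average chi-squared, per-case
Cook's distance / leverage / studentized residuals, scatter exports) drive
the outlier-curation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh import CumulativeDVH, combine_region_dvhs, dvh_from_doses_on_grid
from .geometry import (PlanGeometry, RegionThresholds, ScalarFeatures,
                       compute_ged_histogram, compute_scalar_features,
                       expected_dose, partition_regions)
from .regression import (LinearFit, chi_squared_overfit, cooks_distance,
                         externally_studentized_residuals, forward_stepwise)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCABasis:
    """Mean vector plus orthonormal eigenvectors by descending eigenvalue.

    Eigenvalues follow the sample-covariance convention (divide by n-1),
    so the sum over rows of squared reconstruction error after truncating
    to k components equals ``(n-1) * sum(eigenvalues[k:])``.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray  # (k_total, m), rows orthonormal
    eigenvalues: np.ndarray   # (k_total,), descending
    n_components: int

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.n_components > self.eigenvectors.shape[0]:
            raise ValueError("invalid n_components")


def fit_pca(curves: np.ndarray, variance_threshold: float = 0.95) -> PCABasis:
    """Mean-centred PCA of row-wise curves via SVD.

    Retains the smallest k with cumulative explained variance >= the
    threshold, at least 1.  Degenerate (identical-row) input yields a
    single zero-eigenvalue component.
    """
    X = np.asarray(curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 curves on a common grid")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (X.shape[0] - 1)
    total = eigenvalues.sum()
    if total <= 0:
        return PCABasis(mean=mean, eigenvectors=vt[:1], eigenvalues=eigenvalues[:1],
                        n_components=1)
    cum = np.cumsum(eigenvalues) / total
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = max(1, min(k, eigenvalues.size))
    return PCABasis(mean=mean, eigenvectors=vt, eigenvalues=eigenvalues,
                    n_components=k)


def project_scores(basis: PCABasis, curve: np.ndarray,
                   n_components: int | None = None) -> np.ndarray:
    """PCS of a curve: inner products of the mean-centred curve with the basis."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] != basis.mean.shape[0]:
        raise ValueError("curve grid does not match the PCA basis")
    k = basis.n_components if n_components is None else n_components
    return (curve - basis.mean) @ basis.eigenvectors[:k].T


def reconstruct(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    """Curve from PCS: mean + sum_k score_k * eigenvector_k."""
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    return basis.mean + scores @ basis.eigenvectors[: scores.shape[-1]]


# ---------------------------------------------------------------------------
# Overlap-region model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapModel:
    mean_curve: np.ndarray
    sd_curve: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd_curve < -1e-12):
            raise ValueError("SD curve must be non-negative")


def fit_overlap_model(curves: np.ndarray) -> OverlapModel:
    """Pointwise mean and (population) SD of overlap-region DVH parts."""
    X = np.asarray(curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 overlap curves")
    return OverlapModel(mean_curve=X.mean(axis=0),
                        sd_curve=X.std(axis=0, ddof=0))


# ---------------------------------------------------------------------------
# Training cases
# ---------------------------------------------------------------------------

@dataclass
class TrainingCase:
    """Everything the model needs about one (plan, structure) pair."""

    plan_id: str
    structure: str
    total_dvh: CumulativeDVH
    in_field_part: CumulativeDVH | None
    overlap_part: CumulativeDVH | None
    ged: CumulativeDVH
    features: ScalarFeatures
    region_fractions: dict
    rx_gy: float


def case_from_voxels(plan_id: str, structure: str, geom: PlanGeometry,
                     achieved_dose_gy: np.ndarray, grid: np.ndarray,
                     falloff_sigma_mm: float,
                     thresholds: RegionThresholds = RegionThresholds(),
                     min_region_voxels: int = 5) -> TrainingCase:
    """Partition a voxelized plan and assemble its DVH parts on ``grid``."""
    e = expected_dose(geom, falloff_sigma_mm, thresholds)
    part = partition_regions(e, geom.in_target, geom.rx_gy, thresholds)
    feats = compute_scalar_features(geom, part)
    doses = np.asarray(achieved_dose_gy, dtype=float)

    def region_dvh(region: str) -> CumulativeDVH | None:
        mask = part.mask(region)
        if mask.sum() < min_region_voxels:
            return None
        return dvh_from_doses_on_grid(doses[mask], grid)

    return TrainingCase(
        plan_id=plan_id,
        structure=structure,
        total_dvh=dvh_from_doses_on_grid(doses, grid),
        in_field_part=region_dvh("in_field"),
        overlap_part=region_dvh("overlap"),
        ged=compute_ged_histogram(geom, falloff_sigma_mm, grid, thresholds),
        features=feats,
        region_fractions=dict(part.fractions),
        rx_gy=geom.rx_gy,
    )


# ---------------------------------------------------------------------------
# Diagnostics containers
# ---------------------------------------------------------------------------

@dataclass
class TrainingDiagnostics:
    """Per-structure goodness-of-fit and per-case influence measures."""

    case_ids: list[str]
    r_squared: float                # eigenvalue-weighted over retained PCs
    chi_squared: float              # parameter-average over retained PCs
    per_pc_r_squared: list[float]
    per_pc_chi_squared: list[float]
    cooks: np.ndarray               # (n_cases, n_pcs)
    studentized: np.ndarray         # (n_cases, n_pcs)
    leverage: np.ndarray            # (n_cases, n_pcs)
    flagged_terms: list[str] = field(default_factory=list)

    @property
    def max_cooks(self) -> np.ndarray:
        return self.cooks.max(axis=1)

    @property
    def max_abs_studentized(self) -> np.ndarray:
        return np.abs(self.studentized).max(axis=1)

    @property
    def max_leverage(self) -> np.ndarray:
        return self.leverage.max(axis=1)


@dataclass
class StructureModel:
    """The trained DVH-estimation model for one structure."""

    structure: str
    grid: np.ndarray
    dvh_basis: PCABasis
    ged_basis: PCABasis
    overlap_model: OverlapModel | None
    pc_fits: list[LinearFit]
    predictor_names: list[str]
    predictor_matrix: np.ndarray    # (n_cases, n_predictors), training design
    dvh_scores: np.ndarray          # (n_cases, k_dvh)
    case_ids: list[str]
    diagnostics: TrainingDiagnostics
    transmission_dose_gy: float
    rx_gy: float

    @property
    def n_selected_terms(self) -> int:
        return sum(len(f.terms) for f in self.pc_fits)

    @property
    def complexity(self) -> int:
        """Retained DVH PCs plus selected regression terms — the "number of
        variables needed" that an over-fitting plan inflates."""
        return self.dvh_basis.n_components + self.n_selected_terms

    def predictor_row(self, case: TrainingCase) -> np.ndarray:
        g = project_scores(self.ged_basis, case.ged.volume_fraction,
                           n_components=_ged_candidate_count(self.ged_basis))
        f = case.features
        return np.concatenate([g, [f.oar_volume_cc, f.target_volume_cc,
                                   f.overlap_pct, f.out_of_field_fraction]])


MIN_GED_CANDIDATES = 3  # offer a few trailing GED PCs: they carry the
                        # curvature of the geometry-dose manifold


def _ged_candidate_count(ged_basis: PCABasis) -> int:
    return min(max(ged_basis.n_components, MIN_GED_CANDIDATES),
               ged_basis.eigenvectors.shape[0])


def _predictor_table(cases: list[TrainingCase],
                     ged_basis: PCABasis) -> tuple[np.ndarray, list[str]]:
    k = _ged_candidate_count(ged_basis)
    G = np.vstack([project_scores(ged_basis, c.ged.volume_fraction, n_components=k)
                   for c in cases])
    names = [f"ged_pc{i + 1}" for i in range(G.shape[1])]
    F = np.array([[c.features.oar_volume_cc, c.features.target_volume_cc,
                   c.features.overlap_pct, c.features.out_of_field_fraction]
                  for c in cases])
    return np.column_stack([G, F]), names + ScalarFeatures.names()


def train_structure_model(cases: list[TrainingCase], grid: np.ndarray,
                          variance_threshold: float = 0.95,
                          ged_variance_threshold: float = 0.95,
                          alpha_in: float = 0.05,
                          allow_interactions: bool = False,
                          transmission_dose_gy: float | None = None,
                          min_cases: int = 20,
                          warn: bool = True) -> StructureModel:
    """Train the four-region DVH model for one structure.

    Cases lacking an in-field part (fully overlapped or fully out-of-field
    OARs) contribute to the overlap model only.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    if warn and len(cases) < min_cases:
        import warnings
        warnings.warn(f"training on {len(cases)} cases, below the "
                      f"{min_cases}-plan commissioning floor", stacklevel=2)
    structure = cases[0].structure
    rx = float(np.median([c.rx_gy for c in cases]))
    if transmission_dose_gy is None:
        transmission_dose_gy = RegionThresholds().transmission_floor * rx

    infield_cases = [c for c in cases if c.in_field_part is not None]
    if len(infield_cases) < 2:
        raise ValueError("fewer than 2 cases have an in-field region")
    Y = np.vstack([c.in_field_part.volume_fraction for c in infield_cases])
    dvh_basis = fit_pca(Y, variance_threshold)
    dvh_scores = np.vstack([project_scores(dvh_basis, row) for row in Y])

    G = np.vstack([c.ged.volume_fraction for c in infield_cases])
    ged_basis = fit_pca(G, ged_variance_threshold)
    X, pred_names = _predictor_table(infield_cases, ged_basis)

    pc_fits = [forward_stepwise(dvh_scores[:, k], X, pred_names, alpha_in,
                                allow_interactions)
               for k in range(dvh_basis.n_components)]

    overlap_curves = [c.overlap_part.volume_fraction for c in cases
                      if c.overlap_part is not None]
    overlap_model = (fit_overlap_model(np.vstack(overlap_curves))
                     if len(overlap_curves) >= 2 else None)

    diagnostics = _diagnose(infield_cases, dvh_basis, dvh_scores, pc_fits)
    return StructureModel(
        structure=structure, grid=np.asarray(grid, dtype=float),
        dvh_basis=dvh_basis, ged_basis=ged_basis, overlap_model=overlap_model,
        pc_fits=pc_fits, predictor_names=pred_names, predictor_matrix=X,
        dvh_scores=dvh_scores, case_ids=[c.plan_id for c in infield_cases],
        diagnostics=diagnostics, transmission_dose_gy=float(transmission_dose_gy),
        rx_gy=rx)


def _diagnose(cases: list[TrainingCase], dvh_basis: PCABasis,
              dvh_scores: np.ndarray, pc_fits: list[LinearFit]) -> TrainingDiagnostics:
    n = len(cases)
    k = len(pc_fits)
    cooks = np.zeros((n, k))
    stud = np.zeros((n, k))
    lev = np.zeros((n, k))
    r2s, chi2s = [], []
    for j, fit in enumerate(pc_fits):
        cooks[:, j] = np.minimum(cooks_distance(fit), 1e12)
        stud[:, j] = externally_studentized_residuals(fit)
        lev[:, j] = fit.hat_diag
        r2s.append(fit.r_squared)
        chi2s.append(chi_squared_overfit(fit))
    weights = dvh_basis.eigenvalues[:k]
    wsum = weights.sum()
    r2_pooled = float(np.dot(weights, r2s) / wsum) if wsum > 0 else 0.0
    flagged = sorted({t for f in pc_fits for t in f.flagged_terms})
    return TrainingDiagnostics(
        case_ids=[c.plan_id for c in cases],
        r_squared=r2_pooled, chi_squared=float(np.mean(chi2s)),
        per_pc_r_squared=[float(v) for v in r2s],
        per_pc_chi_squared=[float(v) for v in chi2s],
        cooks=cooks, studentized=stud, leverage=lev, flagged_terms=flagged)


# ---------------------------------------------------------------------------
# Scatter exports
# ---------------------------------------------------------------------------

def export_scatter_data(model: StructureModel) -> list[dict]:
    """Per (PC, selected predictor): points, fitted line, +/-1 and +/-2 SD lines.

    The fitted line for a predictor holds the other selected terms at their
    training means; its slope equals that predictor's regression coefficient.
    """
    out = []
    name_to_col = {nm: j for j, nm in enumerate(model.predictor_names)}
    for k, fit in enumerate(model.pc_fits):
        y = model.dvh_scores[:, k]
        s = float(np.sqrt(max(fit.s2, 0.0))) if np.isfinite(fit.s2) else 0.0
        for term in fit.terms:
            if term not in name_to_col:
                continue  # interaction term: no single predictor axis
            x = model.predictor_matrix[:, name_to_col[term]]
            coef_idx = fit.terms.index(term) + 1  # +1 for intercept
            slope = float(fit.coef[coef_idx])
            # intercept of the partial line: absorb other terms at their means
            intercept = float(fit.coef[0])
            for other_i, other in enumerate(fit.terms):
                if other == term:
                    continue
                col = model.predictor_matrix[:, name_to_col[other]] \
                    if other in name_to_col else None
                if col is not None:
                    intercept += float(fit.coef[other_i + 1]) * float(col.mean())
            out.append({
                "pc": k + 1, "predictor": term,
                "case_ids": list(model.case_ids),
                "x": x.copy(), "y": y.copy(),
                "slope": slope, "intercept": intercept,
                "sd": s,
                "flagged": term in fit.flagged_terms,
            })
    return out
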