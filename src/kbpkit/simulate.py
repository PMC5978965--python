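"""Synthetic radiotherapy plan cohorts with ground-truth outlier labels.

The generator emulates the statistical structure a knowledge-based-planning
model assumes about a training cohort:

* a smooth geometry-to-dose relationship — OAR sparing improves with
  distance from the target, through a per-voxel sparing factor
  ``s(d, q) = floor + (1 - floor) * exp(-d / (sigma_s * (1 + q)))``;
* a latent planner-quality parameter ``q >= 0`` (0 = best achievable);
  larger ``q`` lengthens the sparing fall-off, i.e. the plan spares less
  than the population could achieve — this is the dosimetric-outlier axis;
* population clusters (e.g. ipsilateral vs contralateral geometry regimes)
  realized as mixture components over the per-plan OAR-to-target distance;
* three injectable outlier categories with ground-truth labels:
  **dosimetric** (quality shifted upward), **geometric** (overlap drawn
  from far outside the population), and **over-fitting** (a hidden
  covariate adds a localized DVH bump that no geometric feature explains);
* a ``replan`` oracle that re-draws quality from the unshifted population
  with identical geometry — re-planning lowers the dose of a dosimetric
  outlier but cannot help a geometric one.

All randomness flows from one integer seed through named per-plan
substreams, so injecting outliers never perturbs the other plans.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .geometry import PlanGeometry, RegionThresholds, expected_dose

# substream codes
_GEOM, _MU, _QUALITY, _NOISE, _INJECT, _HIDDEN = 0, 1, 2, 3, 4, 5
_REPLAN_Q, _REPLAN_NOISE = 100, 200


@dataclass(frozen=True)
class RegimeSpec:
    """One geometry regime (mixture component).

    ``dist_mean_mm``/``dist_sd_mm`` give the population distribution of the
    per-plan OAR centroid distance to the target boundary; ``spread_mm`` is
    the within-OAR spatial extent.  Overlap fraction follows from the part
    of the voxel distance distribution below 0.
    """

    weight: float = 1.0
    dist_mean_mm: float = 25.0
    dist_sd_mm: float = 1.5
    spread_mm: float = 14.0


@dataclass(frozen=True)
class StructureSpec:
    name: str = "oar"
    n_voxels: int = 2000
    voxel_volume_cc: float = 0.1


@dataclass(frozen=True)
class QualityModel:
    """Population of planner quality q ~ Normal(mean, sd) truncated at 0.

    With the default mean 0 the population is half-normal: most plans sit
    near the best achievable (q = 0) with a one-sided tail of progressively
    less optimal plans — quality degradation has a floor but no ceiling.
    """

    mean: float = 0.0
    sd: float = 0.45


@dataclass(frozen=True)
class CohortConfig:
    n_plans: int = 40
    rx_gy: float = 78.0
    target_volume_cc: float = 60.0
    structures: tuple = (StructureSpec(),)
    regimes: tuple = (RegimeSpec(),)
    quality: QualityModel = QualityModel()
    noise_sd: float = 0.05
    falloff_sigma_mm: float = 18.0
    sparing_sigma_mm: float = 6.0
    sparing_floor: float = 0.02
    thresholds: RegionThresholds = RegionThresholds()
    seed: int = 0
    min_plans: int = 20

    def __post_init__(self) -> None:
        w = np.array([r.weight for r in self.regimes], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("regime weights must sum to 1")
        if self.n_plans < self.min_plans:
            raise ValueError(f"n_plans must be >= {self.min_plans} "
                             "(commissioning floor for model training)")
        if self.quality.sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.sparing_sigma_mm <= 0 or self.falloff_sigma_mm <= 0:
            raise ValueError("length scales must be > 0")
        if not 0 <= self.sparing_floor < 1:
            raise ValueError("sparing_floor must be in [0, 1)")


@dataclass(frozen=True)
class OutlierSpec:
    """Counts and magnitudes of the injected outlier categories."""

    n_dosimetric: int = 0
    dq_shift: float = 3.0            # in population SDs of q
    n_geometric: int = 0
    overlap_range: tuple = (0.5, 0.7)  # out-of-population overlap fraction
    geometric_spread_factor: float = 0.6  # compact OAR wrapping the target
    n_overfitting: int = 0
    bump_amplitude: float = 0.35     # in-field volume fraction lifted by the bump
    bump_level_range: tuple = (0.35, 0.6)  # bump dose level, as fraction of Rx

    def total(self) -> int:
        return self.n_dosimetric + self.n_geometric + self.n_overfitting

    def __post_init__(self) -> None:
        if min(self.n_dosimetric, self.n_geometric, self.n_overfitting) < 0:
            raise ValueError("outlier counts must be >= 0")
        if self.dq_shift < 0 or self.bump_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class StructureSim:
    """Voxelized geometry and dose of one structure in one synthetic plan."""

    name: str
    distances_mm: np.ndarray
    achieved_dose_gy: np.ndarray
    mu_mm: float                  # per-plan centroid distance (latent)
    spread_mm: float
    voxel_volume_cc: float

    def geometry(self, cfg: CohortConfig) -> PlanGeometry:
        return PlanGeometry(distances_mm=self.distances_mm, rx_gy=cfg.rx_gy,
                            target_volume_cc=cfg.target_volume_cc,
                            voxel_volume_cc=self.voxel_volume_cc)


@dataclass
class SyntheticPlan:
    plan_id: str
    index: int
    cohort_seed: int
    rx_gy: float
    q: float
    cluster_id: int
    structures: dict
    outlier_category: str = "none"
    hidden_bump: tuple | None = None   # (level_gy, amplitude)
    replanned: bool = False
    replan_count: int = 0


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(v) for v in path)))


def _truncated_quality(qm: QualityModel, rng: np.random.Generator) -> float:
    if qm.sd == 0:
        return max(qm.mean, 0.0)
    a = (0.0 - qm.mean) / qm.sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=qm.mean, scale=qm.sd,
                                     random_state=rng))


def sparing_factor(distances_mm: np.ndarray, q: float,
                   cfg: CohortConfig) -> np.ndarray:
    """s(d, q): 1 in the overlap, exponential sparing beyond the target."""
    d = np.asarray(distances_mm, dtype=float)
    scale = cfg.sparing_sigma_mm * (1.0 + q)
    s = cfg.sparing_floor + (1.0 - cfg.sparing_floor) * np.exp(-np.maximum(d, 0.0) / scale)
    return np.where(d <= 0, 1.0, s)


def _noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the stated SD."""
    if sd == 0:
        return np.ones(n)
    sigma_l = np.sqrt(np.log1p(sd ** 2))
    return np.exp(sigma_l * rng.standard_normal(n) - 0.5 * sigma_l ** 2)


def _achieved(ss_distances: np.ndarray, q: float, cfg: CohortConfig,
              noise_rng: np.random.Generator) -> np.ndarray:
    geom = PlanGeometry(distances_mm=ss_distances, rx_gy=cfg.rx_gy,
                        target_volume_cc=cfg.target_volume_cc)
    e = expected_dose(geom, cfg.falloff_sigma_mm, cfg.thresholds)
    s = sparing_factor(ss_distances, q, cfg)
    return e * s * _noise(ss_distances.size, cfg.noise_sd, noise_rng)


def best_achievable_dose(plan: SyntheticPlan, cfg: CohortConfig,
                         structure: str) -> np.ndarray:
    """Noise-free achieved dose at q = 0 — the population's best plan."""
    ss = plan.structures[structure]
    geom = ss.geometry(cfg)
    e = expected_dose(geom, cfg.falloff_sigma_mm, cfg.thresholds)
    return e * sparing_factor(ss.distances_mm, 0.0, cfg)


def _apply_bump(doses: np.ndarray, distances: np.ndarray, level_gy: float,
                amplitude: float, cfg: CohortConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Lift a random subset of in-field voxels to the bump dose level."""
    geom = PlanGeometry(distances_mm=distances, rx_gy=cfg.rx_gy,
                        target_volume_cc=cfg.target_volume_cc)
    e = expected_dose(geom, cfg.falloff_sigma_mm, cfg.thresholds)
    in_field = (distances > 0) & (e >= cfg.thresholds.t_leaf_transmission * cfg.rx_gy)
    idx = np.nonzero(in_field)[0]
    n_lift = int(round(amplitude * idx.size))
    if n_lift == 0:
        return doses
    chosen = rng.choice(idx, size=n_lift, replace=False)
    lifted = level_gy * (1.0 + 0.02 * rng.standard_normal(n_lift))
    out = doses.copy()
    out[chosen] = np.maximum(out[chosen], lifted)
    return out


def _build_plan(cfg: CohortConfig, index: int, q: float, cluster_id: int,
                mu_overrides: dict | None = None,
                spread_overrides: dict | None = None,
                noise_code: int = _NOISE) -> SyntheticPlan:
    """Assemble one plan from its named substreams (deterministic)."""
    structures = {}
    for si, spec in enumerate(cfg.structures):
        regime = cfg.regimes[cluster_id]
        spread = regime.spread_mm
        if spread_overrides and spec.name in spread_overrides:
            spread = spread_overrides[spec.name]
        if mu_overrides and spec.name in mu_overrides:
            mu = mu_overrides[spec.name]
        else:
            mu = regime.dist_mean_mm + regime.dist_sd_mm * _rng(
                cfg.seed, index, si, _MU).standard_normal()
        z = _rng(cfg.seed, index, si, _GEOM).standard_normal(spec.n_voxels)
        distances = mu + spread * z
        achieved = _achieved(distances, q, cfg,
                             _rng(cfg.seed, index, si, noise_code))
        structures[spec.name] = StructureSim(
            name=spec.name, distances_mm=distances, achieved_dose_gy=achieved,
            mu_mm=float(mu), spread_mm=float(spread),
            voxel_volume_cc=spec.voxel_volume_cc)
    return SyntheticPlan(plan_id=f"plan{index:04d}", index=index,
                         cohort_seed=cfg.seed, rx_gy=cfg.rx_gy, q=q,
                         cluster_id=cluster_id, structures=structures)


def generate_cohort(cfg: CohortConfig) -> list[SyntheticPlan]:
    """Generate ``cfg.n_plans`` plans; deterministic given ``cfg.seed``."""
    weights = np.array([r.weight for r in cfg.regimes], dtype=float)
    plans = []
    for i in range(cfg.n_plans):
        r = _rng(cfg.seed, i, 0, _MU)  # regime pick shares the mu substream head
        cluster_id = int(r.choice(len(weights), p=weights))
        q = _truncated_quality(cfg.quality, _rng(cfg.seed, i, 0, _QUALITY))
        plans.append(_build_plan(cfg, i, q, cluster_id))
    return plans


def inject_outliers(cohort: list[SyntheticPlan], spec: OutlierSpec,
                    cfg: CohortConfig, seed: int | None = None) -> list[SyntheticPlan]:
    """Turn selected plans into labelled outliers (others untouched).

    Assignment is disjoint; the victims are drawn without replacement from
    an injection substream of the cohort seed (or ``seed`` if given).
    """
    if spec.total() > len(cohort):
        raise ValueError("more outliers requested than plans available")
    if spec.total() == 0:
        return [copy.deepcopy(p) for p in cohort]
    pick_rng = _rng(cfg.seed if seed is None else seed, 0, 0, _INJECT)
    victims = pick_rng.choice(len(cohort), size=spec.total(), replace=False)
    dosi = set(victims[:spec.n_dosimetric].tolist())
    geo = set(victims[spec.n_dosimetric:spec.n_dosimetric + spec.n_geometric].tolist())
    over = set(victims[spec.n_dosimetric + spec.n_geometric:].tolist())

    out = []
    for i, plan in enumerate(cohort):
        if i not in dosi and i not in geo and i not in over:
            out.append(copy.deepcopy(plan))
            continue
        inj = _rng(cfg.seed, plan.index, 0, _INJECT)
        if i in dosi:
            q_new = plan.q + spec.dq_shift * cfg.quality.sd
            p = _build_plan(cfg, plan.index, q_new, plan.cluster_id)
            p.outlier_category = "dosimetric"
        elif i in geo:
            overlap = inj.uniform(*spec.overlap_range)
            mu_ov, sp_ov = {}, {}
            for s in cfg.structures:
                spread = (cfg.regimes[plan.cluster_id].spread_mm
                          * spec.geometric_spread_factor)
                sp_ov[s.name] = spread
                mu_ov[s.name] = float(-spread * stats.norm.ppf(overlap))
            p = _build_plan(cfg, plan.index, plan.q, plan.cluster_id,
                            mu_overrides=mu_ov, spread_overrides=sp_ov)
            p.outlier_category = "geometric"
        else:
            level = float(inj.uniform(*spec.bump_level_range) * cfg.rx_gy)
            p = copy.deepcopy(plan)
            p.hidden_bump = (level, spec.bump_amplitude)
            for ss in p.structures.values():
                ss.achieved_dose_gy = _apply_bump(
                    ss.achieved_dose_gy, ss.distances_mm, level,
                    spec.bump_amplitude, cfg,
                    _rng(cfg.seed, plan.index, 0, _HIDDEN))
            p.outlier_category = "overfitting"
        out.append(p)
    return out


def replan(plan: SyntheticPlan, cfg: CohortConfig, draw: int = 0) -> SyntheticPlan:
    """Re-plan: fresh quality from the unshifted population, same geometry.

    The hidden covariate of an over-fitting outlier is a property of the
    patient, not the planner, so its DVH bump persists through re-planning.
    """
    q_new = _truncated_quality(cfg.quality,
                               _rng(cfg.seed, plan.index, 0, _REPLAN_Q + draw))
    structures = {}
    for si, (name, ss) in enumerate(plan.structures.items()):
        achieved = _achieved(ss.distances_mm, q_new, cfg,
                             _rng(cfg.seed, plan.index, si, _REPLAN_NOISE + draw))
        if plan.hidden_bump is not None:
            level, amp = plan.hidden_bump
            achieved = _apply_bump(achieved, ss.distances_mm, level, amp, cfg,
                                   _rng(cfg.seed, plan.index, 0, _HIDDEN))
        structures[name] = replace(ss, achieved_dose_gy=achieved)
    return SyntheticPlan(plan_id=plan.plan_id, index=plan.index,
                         cohort_seed=plan.cohort_seed, rx_gy=plan.rx_gy,
                         q=q_new, cluster_id=plan.cluster_id,
                         structures=structures,
                         outlier_category=plan.outlier_category,
                         hidden_bump=plan.hidden_bump, replanned=True,
                         replan_count=plan.replan_count + 1)


def mean_oar_dose(plan: SyntheticPlan, structure: str) -> float:
    return float(plan.structures[structure].achieved_dose_gy.mean())
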