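"""Geometric predictors: region partition, GED histogram, scalar features.

The estimation model decomposes each organ at risk (OAR) into four regions —
overlap (inside the target), in-field, leaf-transmission, and out-of-field —
and predicts the in-field DVH part from geometry.  The geometry enters
through a geometry-based expected-dose (GED) histogram and four scalar
features: OAR volume, target volume, percent overlap with the target, and
the out-of-field volume fraction.

The GED here is a 1-D cumulative histogram of a per-voxel expected dose
driven by the signed distance to the target boundary (negative inside) with
exponential fall-off outside.  Only its principal-component scores feed the
regression, so a 1-D surrogate of the full 3-D construction suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import CumulativeDVH, dvh_from_doses_on_grid

REGIONS = ("overlap", "in_field", "leaf_transmission", "out_of_field")

# a GED histogram is structurally a cumulative DVH of expected dose
GEDHistogram = CumulativeDVH


@dataclass(frozen=True)
class RegionThresholds:
    """Expected-dose cutoffs (as fractions of prescription) defining regions.

    ``t_out_of_field`` and ``t_leaf_transmission`` bound the leaf-transmission
    band; ``transmission_floor`` is the expected-dose floor applied to
    in-field voxels (closed leaves still transmit a few percent of Rx).
    """

    t_out_of_field: float = 0.005
    t_leaf_transmission: float = 0.05
    transmission_floor: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_out_of_field < self.t_leaf_transmission < 1.0):
            raise ValueError("need 0 <= t_out_of_field < t_leaf_transmission < 1")
        if self.transmission_floor < 0:
            raise ValueError("transmission_floor must be >= 0")


@dataclass(frozen=True)
class PlanGeometry:
    """Voxelized OAR geometry relative to the target.

    ``distances_mm`` are signed distances of OAR voxels to the target
    boundary (negative inside the target, i.e. overlap voxels).
    """

    distances_mm: np.ndarray
    rx_gy: float
    target_volume_cc: float
    voxel_volume_cc: float = 0.1

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_mm, dtype=float)
        if d.size == 0:
            raise ValueError("geometry has no voxels")
        if self.rx_gy <= 0 or self.target_volume_cc <= 0 or self.voxel_volume_cc <= 0:
            raise ValueError("rx, target volume, voxel volume must be > 0")
        object.__setattr__(self, "distances_mm", d)

    @property
    def in_target(self) -> np.ndarray:
        return self.distances_mm <= 0.0

    @property
    def oar_volume_cc(self) -> float:
        return float(self.distances_mm.size * self.voxel_volume_cc)


@dataclass(frozen=True)
class RegionPartition:
    labels: np.ndarray  # array of strings from REGIONS
    fractions: dict  # region -> volume fraction

    def mask(self, region: str) -> np.ndarray:
        return self.labels == region


@dataclass(frozen=True)
class ScalarFeatures:
    oar_volume_cc: float
    target_volume_cc: float
    overlap_pct: float
    out_of_field_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_pct <= 100.0):
            raise ValueError("overlap_pct must be in [0, 100]")
        if not (0.0 <= self.out_of_field_fraction <= 1.0):
            raise ValueError("out_of_field_fraction must be in [0, 1]")
        if self.oar_volume_cc <= 0 or self.target_volume_cc <= 0:
            raise ValueError("volumes must be > 0")

    def as_dict(self) -> dict:
        return {
            "oar_volume_cc": self.oar_volume_cc,
            "target_volume_cc": self.target_volume_cc,
            "overlap_pct": self.overlap_pct,
            "out_of_field_fraction": self.out_of_field_fraction,
        }

    @staticmethod
    def names() -> list[str]:
        return ["oar_volume_cc", "target_volume_cc", "overlap_pct",
                "out_of_field_fraction"]


def expected_dose(geom: PlanGeometry, falloff_sigma_mm: float,
                  thresholds: RegionThresholds = RegionThresholds()) -> np.ndarray:
    """Per-voxel geometry-based expected dose.

    Rx inside the target; exponential fall-off ``rx * exp(-d/sigma)`` outside,
    floored at the leaf-transmission level while still in the field and set
    to 0 once the raw fall-off drops below the out-of-field cutoff.
    """
    if falloff_sigma_mm <= 0:
        raise ValueError("falloff_sigma_mm must be > 0")
    d = geom.distances_mm
    rx = geom.rx_gy
    raw = np.where(d <= 0, rx, rx * np.exp(-np.maximum(d, 0.0) / falloff_sigma_mm))
    out = raw < thresholds.t_out_of_field * rx
    e = np.where(out, 0.0, np.maximum(raw, thresholds.transmission_floor * rx))
    e = np.where(d <= 0, rx, e)
    return e


def partition_regions(expected_doses: np.ndarray, in_target: np.ndarray,
                      rx_gy: float,
                      thresholds: RegionThresholds = RegionThresholds()) -> RegionPartition:
    """Label every voxel with one of the four model regions.

    Overlap = inside the target; the rest are split on expected dose:
    below ``t_out_of_field * rx`` -> out-of-field, below
    ``t_leaf_transmission * rx`` -> leaf-transmission, else in-field.
    """
    e = np.asarray(expected_doses, dtype=float)
    t = np.asarray(in_target, dtype=bool)
    if e.shape != t.shape:
        raise ValueError("expected_doses and in_target must have equal length")
    if rx_gy <= 0:
        raise ValueError("rx_gy must be > 0")
    labels = np.full(e.shape, "out_of_field", dtype=object)
    labels[e >= thresholds.t_out_of_field * rx_gy] = "leaf_transmission"
    labels[e >= thresholds.t_leaf_transmission * rx_gy] = "in_field"
    labels[t] = "overlap"
    labels = labels.astype(str)
    n = e.size
    fractions = {r: float(np.sum(labels == r)) / n for r in REGIONS}
    return RegionPartition(labels=labels, fractions=fractions)


def compute_ged_histogram(geom: PlanGeometry, falloff_sigma_mm: float, grid: np.ndarray,
                          thresholds: RegionThresholds = RegionThresholds()) -> CumulativeDVH:
    """Cumulative histogram of the per-voxel expected dose on ``grid``."""
    e = expected_dose(geom, falloff_sigma_mm, thresholds)
    return dvh_from_doses_on_grid(e, grid)


def compute_scalar_features(geom: PlanGeometry,
                            partition: RegionPartition) -> ScalarFeatures:
    """The four scalar predictors of the regression model."""
    n = geom.distances_mm.size
    if n == 0:
        raise ValueError("zero OAR voxels")
    return ScalarFeatures(
        oar_volume_cc=geom.oar_volume_cc,
        target_volume_cc=geom.target_volume_cc,
        overlap_pct=100.0 * partition.fractions["overlap"],
        out_of_field_fraction=partition.fractions["out_of_field"],
    )
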