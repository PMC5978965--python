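"""Cumulative dose-volume histograms (DVHs).

The cumulative DVH is the central object of knowledge-based planning QA:
for a structure it gives, at every dose level ``d``, the fraction of the
structure's volume receiving at least ``d``.  Everything downstream —
per-region PCA modelling, outlier diagnostics, V-metric validation — is
phrased in terms of these curves.

Conventions
-----------
* "volume receiving >= dose"; volume is a fraction in [0, 1] internally
  (percent only in reports).
* Dose bins form a strictly ascending grid starting at 0 Gy; the curve is
  non-increasing with V(0) = 1.
* Queries are linear in dose; doses beyond the grid return 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass(frozen=True)
class StructureDose:
    """Per-voxel absorbed doses of one structure in one plan.

    Parameters
    ----------
    plan_id : str
        Identifier of the treatment plan.
    structure : str
        Structure (organ-at-risk or target) name.
    doses_gy : ndarray
        Per-voxel absorbed dose in Gy, all >= 0, non-empty.
    voxel_volume_cc : float
        Volume represented by each dose sample (uniform sampling), cm^3.
    prescription_dose_gy : float
        Target prescription dose in Gy, > 0.
    """

    plan_id: str
    structure: str
    doses_gy: np.ndarray
    voxel_volume_cc: float = 0.1
    prescription_dose_gy: float = 78.0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses_gy, dtype=float)
        if doses.size == 0:
            raise ValueError("no samples")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if self.prescription_dose_gy <= 0:
            raise ValueError("prescription_dose_gy must be > 0")
        object.__setattr__(self, "doses_gy", doses)

    @property
    def volume_cc(self) -> float:
        return float(self.doses_gy.size * self.voxel_volume_cc)


@dataclass(frozen=True)
class CumulativeDVH:
    """A cumulative DVH: strictly ascending dose grid, non-increasing volume.

    Invariants: ``dose_bins[0] == 0``, ``volume_fraction[0] == 1``,
    volume_fraction non-increasing and in [0, 1].
    """

    dose_bins: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        bins = np.asarray(self.dose_bins, dtype=float)
        vf = np.asarray(self.volume_fraction, dtype=float)
        if bins.ndim != 1 or bins.shape != vf.shape:
            raise ValueError("dose_bins and volume_fraction must be 1-D and equal length")
        if bins.size < 1 or bins[0] != 0.0:
            raise ValueError("dose grid must start at 0 Gy")
        if np.any(np.diff(bins) <= 0):
            raise ValueError("dose grid must be strictly ascending")
        if abs(vf[0] - 1.0) > 1e-9:
            raise ValueError("volume_fraction[0] must be 1")
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("volume_fraction must be non-increasing")
        if vf[-1] < -1e-12 or np.any(vf > 1 + 1e-12):
            raise ValueError("volume_fraction must lie in [0, 1]")
        object.__setattr__(self, "dose_bins", bins)
        object.__setattr__(self, "volume_fraction", vf)

    def resample(self, grid: np.ndarray) -> "CumulativeDVH":
        """Linear interpolation onto a new ascending grid (0 beyond the end)."""
        grid = np.asarray(grid, dtype=float)
        vf = np.interp(grid, self.dose_bins, self.volume_fraction,
                       left=1.0, right=0.0)
        return CumulativeDVH(grid, vf)


@dataclass(frozen=True)
class DVHSummary:
    """Scalar summaries of a cumulative DVH."""

    d_max_gy: float
    d_mean_gy: float
    dvh: CumulativeDVH = field(repr=False)

    def v_at(self, dose_gy: float) -> float:
        """Volume fraction receiving at least ``dose_gy``."""
        return volume_at_dose(self.dvh, dose_gy)

    def d_at(self, volume_fraction: float) -> float:
        """Dose received by at least ``volume_fraction`` of the volume."""
        return dose_at_volume(self.dvh, volume_fraction)


def compute_cumulative_dvh(sd: StructureDose,
                           bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> CumulativeDVH:
    """Build the cumulative DVH of a dose sample by direct counting.

    The grid spans [0, max(doses) + bin_width] so the final bin is empty;
    at each bin edge d, V(d) = (#doses >= d) / N.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses = sd.doses_gy
    n_bins = int(np.ceil((doses.max() + bin_width_gy) / bin_width_gy)) + 1
    grid = np.arange(n_bins, dtype=float) * bin_width_gy
    return dvh_from_doses_on_grid(doses, grid)


def dvh_from_doses_on_grid(doses_gy: np.ndarray, grid: np.ndarray) -> CumulativeDVH:
    """Cumulative DVH of a raw dose vector evaluated on a given grid."""
    doses = np.sort(np.asarray(doses_gy, dtype=float))
    if doses.size == 0:
        raise ValueError("no samples")
    # count of doses >= d via searchsorted on the sorted vector
    vf = (doses.size - np.searchsorted(doses, grid, side="left")) / doses.size
    vf[0] = 1.0
    return CumulativeDVH(np.asarray(grid, dtype=float), vf)


def volume_at_dose(dvh: CumulativeDVH, dose_gy: float) -> float:
    """V(d): linear interpolation; 0 beyond the last bin edge."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    return float(np.interp(dose_gy, dvh.dose_bins, dvh.volume_fraction,
                           left=1.0, right=0.0))


def dose_at_volume(dvh: CumulativeDVH, volume_fraction: float) -> float:
    """D(v): highest dose at which the curve still reaches ``volume_fraction``."""
    v = float(volume_fraction)
    vf = dvh.volume_fraction
    if v > vf[0]:
        return 0.0
    if v < vf[-1]:
        return float(dvh.dose_bins[-1])
    # walk from the high-dose end: first index where vf >= v
    idx = np.nonzero(vf >= v)[0][-1]
    if idx == vf.size - 1 or vf[idx] == v:
        return float(dvh.dose_bins[idx])
    # interpolate within the step [idx, idx+1] where vf drops below v
    d0, d1 = dvh.dose_bins[idx], dvh.dose_bins[idx + 1]
    v0, v1 = vf[idx], vf[idx + 1]
    if v0 == v1:
        return float(d1)
    return float(d0 + (v0 - v) / (v0 - v1) * (d1 - d0))


def dvh_summary(dvh: CumulativeDVH) -> DVHSummary:
    """d_max (largest bin edge with V > 0) and trapezoid d_mean."""
    nonzero = np.nonzero(dvh.volume_fraction > 0)[0]
    d_max = float(dvh.dose_bins[nonzero[-1]]) if nonzero.size else 0.0
    d_mean = float(np.trapezoid(dvh.volume_fraction, dvh.dose_bins))
    return DVHSummary(d_max_gy=d_max, d_mean_gy=d_mean, dvh=dvh)


def combine_region_dvhs(parts: list[tuple[CumulativeDVH, float]]) -> CumulativeDVH:
    """Volume-weighted pointwise combination of region sub-DVHs.

    All parts must share one dose grid; weights are the region volume
    fractions and must sum to 1.  The combined curve is exactly the DVH of
    the pooled dose sample when the parts were built from a voxel partition
    on the same grid.
    """
    if not parts:
        raise ValueError("no parts to combine")
    weights = np.array([w for _, w in parts], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"region weights sum to {weights.sum():.8f}, expected 1")
    grid = parts[0][0].dose_bins
    for dvh, _ in parts[1:]:
        if dvh.dose_bins.shape != grid.shape or not np.array_equal(dvh.dose_bins, grid):
            raise ValueError("all parts must share one dose grid; resample first")
    vf = np.zeros_like(grid)
    for dvh, w in parts:
        vf = vf + w * dvh.volume_fraction
    vf = np.clip(vf, 0.0, 1.0)
    vf[0] = 1.0
    # guard against floating-point wiggle at the 1e-15 level
    vf = np.minimum.accumulate(vf)
    return CumulativeDVH(grid, vf)


def read_dvh_csv(path) -> CumulativeDVH:
    """Read the package's DVH CSV dialect (``dose_gy,volume_pct``).

    Descending files are sorted; a file that is non-monotone in volume
    after sorting by dose is rejected with the offending row number.
    """
    import csv

    rows: list[tuple[float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != ["dose_gy", "volume_pct"]:
            raise ValueError(f"{path}: expected header 'dose_gy,volume_pct', got {header!r}")
        for row in reader:
            rows.append((float(row[0]), float(row[1])))
    rows.sort(key=lambda r: r[0])
    doses = np.array([r[0] for r in rows])
    vf = np.array([r[1] for r in rows]) / 100.0
    for i in range(1, len(vf)):
        if vf[i] > vf[i - 1] + 1e-9:
            raise ValueError(f"{path}: volume increases with dose at row {i + 1}")
    return CumulativeDVH(doses, np.clip(vf, 0.0, 1.0))


def write_dvh_csv(path, dvh: CumulativeDVH) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dose_gy,volume_pct\n")
        for d, v in zip(dvh.dose_bins, dvh.volume_fraction):
            fh.write(f"{d:.6g},{100.0 * v:.10g}\n")
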