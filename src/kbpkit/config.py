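"""Run configuration: every threshold of the commissioning workflow.

The two thresholds with literature standing are Cook's distance 3.0
(influence) and chi-squared 1.3 (severe over-fitting); the rest are
declared gap-fills with the defaults documented per field.  Every value is
echoed into all outputs so a run is fully reproducible from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    # influence / outlier flags
    cooks_threshold: float = 3.0          # Cook's distance -> influential
    residual_threshold: float = 3.0       # |studentized residual| hard flag
    robust_z_threshold: float = 3.5       # feature modified z (median/MAD)
    scatter_sd: float = 1.25              # scatter-plot band: potential outliers
    # over-fitting monitor
    chi_squared_threshold: float = 1.3    # "no severe over-fitting" above this
    overfit_recon_ratio: float = 4.0      # leave-out PCA error ratio -> overfitting
    overfit_recon_floor: float = 0.005    # absolute RMS floor (volume fraction)
    # model fitting
    alpha_in: float = 0.05                # stepwise entry p-value
    variance_threshold: float = 0.95      # DVH PCA retained variance
    ged_variance_threshold: float = 0.95  # GED PCA retained variance
    allow_interactions: bool = False
    # curation loop
    replan_margin_sd: float = 3.0         # dosimetric if replan drop > this many
                                          # replan-scale SDs
    n_replan_draws: int = 16              # replan-trial draws (median drop used)
    n_scale_plans: int = 16               # plans sampled for the cohort replan scale
    n_scale_draws: int = 10               # draws per sampled plan
    max_iter: int = 10
    batch: int = 2                        # cases acted on per iteration
    stop_delta_r2: float = 0.005          # "no more significant improvement"
    stop_delta_chi2: float = 0.01
    cluster_policy: str = "split"         # or "merge"
    cluster_bic_margin: float = 20.0      # BIC gain required to prefer larger k
    min_plans: int = 20
    # estimation / reporting
    band_z: float = 1.0                   # SD multiplier of the estimate band
    bin_width_gy: float = 0.05
    grid_max_factor: float = 1.3          # grid spans [0, factor * rx]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_policy not in ("split", "merge"):
            raise ValueError("cluster_policy must be 'split' or 'merge'")
        for name in ("cooks_threshold", "residual_threshold", "robust_z_threshold",
                     "scatter_sd", "chi_squared_threshold", "bin_width_gy",
                     "band_z", "replan_margin_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha_in < 1:
            raise ValueError("alpha_in must be in (0, 1)")
        if self.batch < 1 or self.max_iter < 1:
            raise ValueError("batch and max_iter must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, embedded in outputs."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
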