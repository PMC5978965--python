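import numpy as np
import pytest

from kbpkit import CohortConfig, QualityModel, RunConfig, StructureSpec
from kbpkit.curation import _build_cases, make_grid
from kbpkit.simulate import generate_cohort


@pytest.fixture
def run_cfg():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def build_cases(cohort, cohort_cfg, grid, structure="oar"):
    return _build_cases(cohort, structure, cohort_cfg, grid)


@pytest.fixture
def small_cohort():
    """A 24-plan default cohort with its grid (cheap, shared)."""
    cfg = CohortConfig(n_plans=24, seed=42)
    grid = make_grid(cfg, RunConfig())
    return cfg, generate_cohort(cfg), grid


@pytest.fixture
def noise_free_cohort():
    """Quality and dose noise both zero: DVHs are pure geometry."""
    cfg = CohortConfig(n_plans=30, seed=9, noise_sd=0.0,
                       quality=QualityModel(0.0, 0.0),
                       structures=(StructureSpec(n_voxels=8000),))
    grid = make_grid(cfg, RunConfig())
    return cfg, generate_cohort(cfg), grid
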