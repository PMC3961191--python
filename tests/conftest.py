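import numpy as np
import pytest

import facebrim as fb
from facebrim.morphometry import symmetric_components


@pytest.fixture(scope="session")
def mask5():
    return fb.make_mask_grid(5, 5)


@pytest.fixture(scope="session")
def small_cohort():
    """80 individuals on a 10x11 grid; all latent effects recorded."""
    return fb.simulate_cohort(
        fb.CohortConfig(n_individuals=80, grid_rows=10, grid_cols=11, seed=7)
    )


@pytest.fixture(scope="session")
def small_aligned(small_cohort):
    sample = fb.generalized_procrustes(
        small_cohort.configurations, small_cohort.mask, include_reflections=True
    )
    return fb.project_tangent(sample)


@pytest.fixture(scope="session")
def small_shape_space(small_aligned):
    sym, _ = symmetric_components(small_aligned)
    space = fb.fit_shape_pca(sym, 0.98, center=small_aligned.consensus)
    return sym, space
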