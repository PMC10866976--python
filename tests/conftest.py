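import numpy as np
import pytest

from brainpad_lab.morphometry import VoxelGrid
from brainpad_lab.synthcohort import CohortSpec, generate_phenotypes, generate_tissue_maps


def make_grid(values, spacing=8.0, mask=None, tissue="GM"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VoxelGrid(values=values, spacing=(spacing,) * 3, mask=mask, tissue=tissue)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_hc_train=60, n_hc_holdout=12, n_pd=50, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    pheno = generate_phenotypes(small_spec)
    maps = generate_tissue_maps(pheno, small_spec)
    return pheno, maps
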