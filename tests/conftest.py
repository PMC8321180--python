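import numpy as np
import pytest

from recistnet.network import ArchitectureSpec
from recistnet.synthetic_cohort import (
    ClassImagingParams,
    CohortConfig,
    SyntheticLesionSpec,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Smallest spec exercising every layer type (non-local, dense, FC)."""
    return ArchitectureSpec(
        input_shape=(4, 6, 6),
        stem_channels=3,
        dense_block_layers=(2, 1),
        nonlocal_counts=(1, 1),
        growth=2,
        fc_widths=(5, 2),
        clinical_dim=3,
        nonlocal_inner=2,
    )


@pytest.fixture
def basic_lesion_spec():
    return SyntheticLesionSpec(
        center_voxel=(12, 40, 40),
        axes_mm=(8.0, 14.0, 12.0),
        class_label="C1",
        texture_contrast=0.1,
        visible_slices=16,
        noise_sd=5.0,
    )


def small_cohort_config(n1=8, n2=12, train=(4, 8)):
    return CohortConfig(
        n_class1=n1,
        n_class2=n2,
        lesions_per_patient=(1, 2),
        train_counts=train,
        class1=ClassImagingParams(60.0, 0.05),
        class2=ClassImagingParams(180.0, 0.15),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """20-lesion cohort reused across tests (generation is deterministic)."""
    return generate_cohort(small_cohort_config(), seed=7)
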