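import numpy as np
import pytest

from seqradiomics.simulate import (CohortSpec, PhantomSpec, TableSpec,
                                   generate_feature_table,
                                   generate_image_cohort)

#: Small phantom geometry used throughout the suite: 32^3 grid at 1.25 mm
#: with a ~7x6x5 mm semi-axis lesion (a few hundred ROI voxels).
SMALL_PHANTOM = dict(grid_shape=(32, 32, 32), spacing=(1.25, 1.25, 1.25),
                     lesion_semi_axes_mm=(7.0, 6.0, 5.0))


@pytest.fixture(scope="session")
def small_phantom_spec():
    return PhantomSpec(**SMALL_PHANTOM, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(small_phantom_spec):
    """Two phantom subjects (one TN, one Luminal A)."""
    from seqradiomics.simulate import generate_phantom_subject

    return [
        generate_phantom_subject(small_phantom_spec, "TN", seed=1,
                                 subject_id="S000_TN"),
        generate_phantom_subject(small_phantom_spec, "LuminalA", seed=2,
                                 subject_id="S001_LuminalA"),
    ]


@pytest.fixture(scope="session")
def tiny_static_table(tiny_cohort):
    from seqradiomics.extract import extract_static_features

    return extract_static_features(tiny_cohort)


@pytest.fixture(scope="session")
def planted_table():
    """134-subject, 500-feature table with 10 planted informative columns."""
    return generate_feature_table(TableSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
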