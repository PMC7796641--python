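import numpy as np
import pytest

from blowcore.synthetic_cohort import CohortParams, generate_cohort
from blowcore.tables_io import CountTable, SampleRecord


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with full structure (cores, water, contaminants)."""
    params = CohortParams(
        n_subjects=6, weeks=(2, 6, 11, 19), n_blow_taxa=120, core_size_mean=25,
        n_water_taxa=40, n_contam_taxa=20, n_water_samples=8,
        n_pos_controls=1, n_neg_controls=3, n_extraction_blanks=2,
        library_size_mean=12000, library_size_sd=4000,
        control_library_mean=10000, control_library_sd=2000,
        rng_seed=42,
    )
    return generate_cohort(params)


@pytest.fixture()
def toy_table():
    counts = np.array(
        [
            [5, 0, 3, 2],
            [1, 4, 0, 2],
            [0, 2, 2, 6],
        ]
    )
    return CountTable(("s1", "s2", "s3"), ("t1", "t2", "t3", "t4"), counts)


@pytest.fixture()
def toy_metadata():
    return [
        SampleRecord("s1", "D1", "blow", week=2),
        SampleRecord("s2", "D1", "blow", week=6),
        SampleRecord("s3", "D2", "blow", week=2),
    ]
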