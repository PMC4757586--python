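"""Shared fixtures: one small planted-truth world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from p53mirnet import (
    generate_mirna_reference,
    generate_read_libraries,
    load_published_dem_table,
    make_study_like_truth,
)


@pytest.fixture(scope="session")
def published_dems():
    return load_published_dem_table()


@pytest.fixture(scope="session")
def small_reference():
    """20 miRNAs on a 2 x 2 Mb toy genome."""
    return generate_mirna_reference(n_mirnas=20, seed=42)


@pytest.fixture(scope="session")
def study_reference():
    """50 miRNAs — large enough to hold the 33-DEM study-like truth."""
    return generate_mirna_reference(n_mirnas=50, seed=7)


@pytest.fixture(scope="session")
def study_truth(study_reference):
    return make_study_like_truth(study_reference, seed=7)


@pytest.fixture(scope="session")
def small_libraries(small_reference):
    truth = make_study_like_truth(
        small_reference, seed=3, n_up=3, n_down=4, n_bound=5, n_multi=2,
    )
    libs = generate_read_libraries(small_reference, truth, n_reads=20_000, seed=3)
    return libs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
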