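import numpy as np
import pytest

from shapecov.shape import ShapeTable
from shapecov.simulate import CovariationSpec, make_cohort, make_shape_table
from shapecov._seq import all_kmers, canonical


@pytest.fixture(scope="session")
def shape_table() -> ShapeTable:
    """A synthetic but fully valid pentamer table (AT-dependent MGW)."""
    return make_shape_table(seed=7)


@pytest.fixture(scope="session")
def constant_table() -> ShapeTable:
    """Every pentamer carries MGW 5.0, ProT −7, Roll 2/2, HelT 34/34."""
    records = {
        p: {"mgw": 5.0, "prot": -7.0, "roll": (2.0, 2.0), "helt": (34.0, 34.0)}
        for p in {canonical(m) for m in all_kmers(5)}
    }
    return ShapeTable.from_records(records)


@pytest.fixture(scope="session")
def small_bundle():
    """An 8-protein synthetic cohort: fast enough for smoke/pipeline tests."""
    return make_cohort(CovariationSpec(n_proteins=8, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
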