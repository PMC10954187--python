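"""Shared fixtures: a synthetic floxed locus and its determinant set."""

import numpy as np
import pytest

from mosaicscreen import derive_determinants, make_flox_locus
from mosaicscreen.seqio import Read


@pytest.fixture(scope="session")
def flox_locus():
    return make_flox_locus(seed=7, length=2000, loxp_positions=(600, 1300))


@pytest.fixture(scope="session")
def flox_dset(flox_locus):
    return derive_determinants(flox_locus, mode="insert")


def make_read(read_id, bases, qual=30):
    return Read(read_id, bases, np.full(len(bases), qual, dtype=np.int64))


@pytest.fixture
def read_factory():
    return make_read
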