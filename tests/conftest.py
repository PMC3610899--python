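import numpy as np
import pytest

from amplotype import (
    default_allele_library,
    default_motif_config,
    Read,
)


def make_read(sequence, qual=40, read_id="r", subject_id=None, quals=None):
    """Read with uniform (or explicit) qualities."""
    if quals is None:
        quals = np.full(len(sequence), qual, dtype=np.int16)
    return Read(read_id=read_id, sequence=sequence, quals=np.asarray(quals),
                subject_id=subject_id)


@pytest.fixture(scope="session")
def library():
    return default_allele_library()


@pytest.fixture(scope="session")
def motif_config():
    return default_motif_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
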