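import numpy as np
import pytest

from crystkit.seq_core import SequenceRecord, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_records(seqs, prefix="S", moltype="protein", mature=False):
    return [
        SequenceRecord(id=f"{prefix}{i}", seq=s, moltype=moltype, mature=mature)
        for i, s in enumerate(seqs)
    ]


@pytest.fixture()
def small_family():
    """Four related sequences with known pairwise relationships."""
    return make_records([
        "ACDEFGHIKLMNPQRSTVWY",
        "ACDEFGHIKLMNPQRSTVWF",
        "ACDEFGHIKLMNPQRSTAWY",
        "PCDEFGHIKLMNPQRSTVWY",
    ])
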