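import numpy as np
import pytest

from himsa.seqio import SequenceRecord, SequenceSet
from himsa.state import AlignmentState


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_ac():
    """Two identical 'AC' sequences, both fully aligned to two columns."""
    seqs = SequenceSet(
        [SequenceRecord("a", "a", "AC"), SequenceRecord("b", "b", "AC")]
    )
    aln = AlignmentState(np.array([[0, 1], [0, 1]]), np.array([2, 2]))
    return seqs, aln


def make_seqs(strings, weights=None):
    records = []
    for i, s in enumerate(strings):
        w = 1.0 if weights is None else weights[i]
        records.append(SequenceRecord(f"s{i}", f"s{i}", s, w))
    return SequenceSet(records)
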