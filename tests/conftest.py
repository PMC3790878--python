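import numpy as np
import pytest

from mgsim.seq_io import AlignmentRecord, GenomeDB


@pytest.fixture
def tiny_db():
    return GenomeDB({"gA": "ACGT" * 250, "gB": "TTGACA" * 200})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mapped(read_id, genome_id, start, cigar, md=None, nm=None, sequence=None):
    """Shorthand for a mapped AlignmentRecord in tests."""
    return AlignmentRecord(
        read_id=read_id,
        genome_id=genome_id,
        start=start,
        cigar=cigar,
        md=md,
        nm=nm,
        is_mapped=True,
        sequence=sequence,
    )


def unmapped(read_id):
    return AlignmentRecord(
        read_id=read_id, genome_id=None, start=-1, cigar=[], is_mapped=False
    )
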