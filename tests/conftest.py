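import numpy as np
import pytest

from orphanomics.transcriptome import SeqReadRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_reads(rng, n, length=100, low_q_tail=True):
    """Reads with optional planted low-quality tails at both ends."""
    reads = []
    for i in range(n):
        bases = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=length))
        quals = rng.integers(25, 41, size=length)
        if low_q_tail:
            head = int(rng.integers(0, 12))
            tail = int(rng.integers(0, 12))
            if head:
                quals[:head] = rng.integers(2, 15, size=head)
            if tail:
                quals[-tail:] = rng.integers(2, 15, size=tail)
        reads.append(SeqReadRecord(f"read{i}", bases, tuple(int(q) for q in quals)))
    return reads
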