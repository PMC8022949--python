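import numpy as np
import pytest

from wavyselect.io_formats import LongRead
from wavyselect.simulate import (
    SimParams,
    simulate_cluster_reads,
    simulate_transcriptome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_reads(rng, n, min_len=50, max_len=500, prefix="r"):
    """Plain random reads with unique ids."""
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        out.append(LongRead(f"{prefix}{i}", seq))
    return out


def simulated_cluster(seed, n_iso, reads_per_isoform=45):
    """One gene's cluster under the standard study conditions: >= 30
    full-length reads per isoform at 70% full-length, 5% total error,
    isoform lengths >= 300 bp apart."""
    params = SimParams(
        seed=seed,
        n_genes=1,
        isoforms_per_gene=(n_iso, n_iso),
        reads_per_cluster=reads_per_isoform * n_iso,
    )
    transcripts = simulate_transcriptome(params)
    reads, labels = simulate_cluster_reads(transcripts, params)
    return transcripts, reads, labels
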