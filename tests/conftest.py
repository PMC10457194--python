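import numpy as np
import pytest

from kappacascade.peakcall import TagLibrary


def make_library(chrom_lengths, tags, sample_id="s", assay="chip", factor="RelA",
                 time_h=1, replicate=1):
    """Build a TagLibrary from a list of (chrom, pos, strand) tuples."""
    positions = {c: {"+": [], "-": []} for c in chrom_lengths}
    for chrom, p, strand in tags:
        positions[chrom][strand].append(p)
    positions = {
        c: {s: np.sort(np.array(v, dtype=np.int64)) for s, v in strands.items()}
        for c, strands in positions.items()
    }
    return TagLibrary(sample_id=sample_id, assay=assay, factor=factor,
                      time_h=time_h, replicate=replicate,
                      chrom_lengths=dict(chrom_lengths), positions=positions)


@pytest.fixture
def small_dataset():
    """Small but complete synthetic dataset shared across integration tests."""
    from kappacascade.simdata import SimConfig, simulate_dataset
    return simulate_dataset(SimConfig(seed=11))
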