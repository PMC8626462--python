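import numpy as np
import pytest

from bafmap.intervals import GenomicInterval, Peak, PeakSet


def make_peaks(factor, triples):
    """Build a PeakSet from (chrom, start, end) or (chrom, start, end, name)."""
    peaks = []
    for i, t in enumerate(triples):
        name = t[3] if len(t) > 3 else f"{factor}_{i}"
        peaks.append(Peak(GenomicInterval(t[0], t[1], t[2]), name))
    return PeakSet(factor, peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
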