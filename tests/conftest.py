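import numpy as np
import pytest

from primedpeaks.intervals import GenomicInterval, Peak, TssRecord
from primedpeaks.motifs import PositionWeightMatrix


def make_peak(chrom, start, end, name="", summit=None):
    return Peak(GenomicInterval(chrom, start, end, ".", name), summit_offset=summit)


@pytest.fixture
def sharp_pwm():
    """Width-6 near-consensus PWM (consensus ACGTAC) on uniform background."""
    cons = [0, 1, 2, 3, 0, 1]
    probs = np.full((6, 4), 0.03)
    probs[np.arange(6), cons] = 0.91
    probs /= probs.sum(axis=1, keepdims=True)
    return PositionWeightMatrix("toy", probs, np.full(4, 0.25))


@pytest.fixture
def tiny_tss():
    return [
        TssRecord("geneA", "chr1", 10_000, "+"),
        TssRecord("geneB", "chr1", 50_000, "-"),
        TssRecord("geneC", "chr2", 20_000, "+"),
    ]
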