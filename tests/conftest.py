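import numpy as np
import pytest

from vntrscope.anchors import AnchorSegment
from vntrscope.config import ScanConfig


@pytest.fixture
def scan_cfg():
    return ScanConfig()


def make_anchor(a_start, length, diag, identity=1.0):
    """Shorthand for an exact anchor segment on one diagonal."""
    matches = int(round(length * identity))
    return AnchorSegment(
        a_start=a_start, a_end=a_start + length,
        b_start=a_start + diag, b_end=a_start + diag + length,
        matches=matches, score=5 * matches - 4 * (length - matches),
        identity=identity)


def random_seq(seed, n, gc=0.5):
    from vntrscope.simgen import _random_seq, _rng
    return _random_seq(_rng(seed), n, gc)
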