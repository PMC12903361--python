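import numpy as np
import pytest

from conftest import make_anchor, random_seq
from vntrscope import simgen
from vntrscope.config import ScanConfig
from vntrscope.detector import (DetectorConfig, RepeatBlock, VntrCall,
                                detect_blocks, estimate_period,
                                flag_polymorphic, score_confidence)
from vntrscope.pipeline import pair_anchors

CFG = ScanConfig()
DCFG = CFG.detector_config()


def detect_pair(seq_a, seq_b, gene="g"):
    anchors = pair_anchors(seq_a, seq_b, CFG)
    return detect_blocks(anchors, len(seq_a), len(seq_b), DCFG, gene)


# ---------------------------------------------------------- estimate_period

@pytest.mark.parametrize(
    "diags,expected",
    [
        ([0, 42, 84, 126], 42),
        ([0, 84], 84),
        ([84], 84),              # a single observation is its own period
        ([0, 40, 42, 84], 42),   # 40 absorbed as 42 +- tolerance
        ([0, -42, 42, -84, 84], 42),
    ],
)
def test_fundamental_period_from_diagonal_offsets(diags, expected):
    anchors = [make_anchor(0, 500 if d == 0 else 100, d) for d in diags]
    assert estimate_period(anchors) == expected


def test_no_off_diagonal_anchors_gives_no_period():
    assert estimate_period([make_anchor(0, 500, 0)]) is None
    assert estimate_period([]) is None


# ------------------------------------------------------------ detect_blocks

def test_ifi207_style_pair_yields_one_block():
    """11 vs 25 exact copies of a 42 bp unit with 1 kb unique flanks."""
    seq_a, seq_b, truth = simgen.gen_vntr_pair(42, 11, 25, 0.0, 1000, seed=7)
    blocks = detect_pair(seq_a, seq_b)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.unit_len == 42
    assert b.copies_a == pytest.approx(11, abs=0.5)
    assert b.copies_b == pytest.approx(25, abs=0.5)
    assert b.r == pytest.approx(25 / 11, rel=0.05)
    assert b.confidence > 0.9


def test_five_copy_array_rejected_six_copy_kept():
    for copies, n_expected in [(3, 0), (5, 0), (6, 1)]:
        sa, sb, _ = simgen.gen_vntr_pair(100, copies, copies, 0.0, 1000,
                                         seed=200 + copies)
        assert len(detect_pair(sa, sb)) == n_expected, copies


def test_two_arrays_with_unique_spacer_are_two_blocks():
    rng = np.random.default_rng(5)
    u1 = simgen._random_seq(rng, 40)
    u2 = simgen._random_seq(rng, 55)
    parts = [simgen._random_seq(rng, 1000), u1 * 8,
             simgen._random_seq(rng, 2000), u2 * 8,
             simgen._random_seq(rng, 1000)]
    seq = "".join(parts)
    blocks = detect_pair(seq, seq)
    assert len(blocks) == 2
    assert [b.unit_len for b in blocks] == [40, 55]


def test_microhomology_scatter_rejected():
    """Ultra-short anchors covering little of their bounding box must not
    be annotated, even when their diagonals suggest a period."""
    anchors = [make_anchor(0, 1000, 0)]
    for i in range(6):
        a0 = 170 * i
        anchors.append(make_anchor(a0, 14, 100))
        anchors.append(make_anchor(a0, 14, 200))
    blocks = detect_blocks(anchors, 1100, 1400, DCFG)
    assert blocks == []


def test_empty_anchor_list_gives_no_blocks():
    assert detect_blocks([], 1000, 1000, DCFG) == []


def test_detection_is_deterministic():
    sa, sb, _ = simgen.gen_vntr_pair(35, 9, 14, 0.02, 800, seed=77)
    one = detect_pair(sa, sb)
    two = detect_pair(sa, sb)
    assert one == two


def test_swap_maps_r_to_its_inverse():
    sa, sb, _ = simgen.gen_vntr_pair(42, 11, 25, 0.0, 1000, seed=7)
    (fwd,) = detect_pair(sa, sb)
    (rev,) = detect_pair(sb, sa)
    assert rev.r == pytest.approx(1 / fwd.r, rel=0.02)


def test_divergent_array_recovered():
    sa, sb, _ = simgen.gen_vntr_pair(60, 10, 18, 0.04, 1000, seed=123)
    (b,) = detect_pair(sa, sb)
    assert b.unit_len == 60


# --------------------------------------------------------- score_confidence

def test_noiseless_exact_array_scores_one():
    seq_a, seq_b, _ = simgen.gen_vntr_pair(42, 11, 25, 0.0, 1000, seed=7)
    anchors = pair_anchors(seq_a, seq_b, CFG)
    (block,) = detect_blocks(anchors, len(seq_a), len(seq_b), DCFG)
    assert block.confidence == pytest.approx(1.0)
    assert score_confidence(block, anchors, DCFG) == pytest.approx(1.0)


def test_half_missing_diagonals_full_coverage_scores_half():
    # unit 100; spans 1200 x 900 -> 12 + 9 - 1 = 20 expected diagonals;
    # anchors provide 10 of them with complete box coverage on both axes.
    block = RepeatBlock("g", (0, 1200), (0, 900), 100, 12.0, 9.0,
                        900 / 1200, 0.0, 10)
    anchors = [make_anchor(0, 900, 0), make_anchor(900, 300, -300)]
    for k in (1, 2, 3, 4, 5, 6):
        anchors.append(make_anchor(0, 50, 100 * k))
    for k in (-1, -2):
        anchors.append(make_anchor(300, 50, 100 * k))
    assert score_confidence(block, anchors, DCFG) == pytest.approx(0.5)


def test_block_without_anchors_is_a_contract_violation():
    block = RepeatBlock("g", (0, 100), (0, 100), 10, 10, 10, 1.0, 0.0, 0)
    with pytest.raises(ValueError):
        score_confidence(block, [], DCFG)


# --------------------------------------------------------- flag_polymorphic

def _call(r, confidence=1.0):
    block = RepeatBlock("g", (0, 462), (0, int(462 * r)), 42,
                        11.0, 11.0 * r, r, confidence, 30)
    return VntrCall(gene_id="g", strain="s", blocks=(block,))


@pytest.mark.parametrize("r,flagged,reason", [
    (2.27, True, "ratio_high"),   # 462 vs 1050 bp
    (1.0, False, "none"),
    (0.95, False, "none"),
    (1.15, True, "ratio_high"),
    (0.85, True, "ratio_low"),
    (0.9, False, "none"),         # boundaries themselves are inside the band
    (1.1, False, "none"),
])
def test_r_band_flagging(r, flagged, reason):
    (out,) = flag_polymorphic([_call(r)], DCFG)
    assert (out.flagged, out.reason) == (flagged, reason)


def test_low_confidence_blocks_are_ignored():
    (out,) = flag_polymorphic([_call(2.0, confidence=0.80)], DCFG)
    assert not out.flagged
    (out,) = flag_polymorphic([_call(2.0, confidence=0.81)], DCFG)
    assert out.flagged


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        DetectorConfig(r_low=1.2)
    with pytest.raises(ValueError):
        DetectorConfig(min_confidence=1.5)
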