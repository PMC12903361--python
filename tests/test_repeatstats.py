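import itertools

import numpy as np
import pytest

from vntrscope import simgen
from vntrscope.detector import RepeatBlock, VntrCall
from vntrscope.repeatstats import (decompose_units, gc_content,
                                   gc_enrichment_test, nucleotide_diversity,
                                   summarize_gene)


def _block(span, unit, gene="g"):
    return RepeatBlock(gene_id=gene, a_span=span, b_span=span, unit_len=unit,
                       copies_a=(span[1] - span[0]) / unit,
                       copies_b=(span[1] - span[0]) / unit,
                       r=1.0, confidence=1.0, n_diagonals=5)


# ---------------------------------------------------------- decompose_units

def test_exact_array_decomposes_cleanly():
    out = decompose_units("ACGACGACG", _block((0, 9), 3))
    assert out.units == ("ACG", "ACG", "ACG")
    assert out.copies == pytest.approx(3.0)
    assert out.pi == 0.0


def test_phase_scan_recovers_frame_with_overhang():
    # 11 bp containing three ACG copies; the trailing A continues the
    # period, the leading T does not.
    out = decompose_units("TACGACGACGA", _block((0, 11), 3))
    assert out.units == ("ACG", "ACG", "ACG")
    assert 3.0 <= out.copies <= 11 / 3


def test_span_shorter_than_unit_rejected():
    with pytest.raises(ValueError):
        decompose_units("ACGT", _block((0, 4), 5))


def test_phase_choice_is_rotation_invariant_for_exact_arrays():
    unit = "ACGTTGACTC"
    arr = unit * 8
    base = decompose_units(arr, _block((0, 80), 10))
    doubled = unit + arr + unit
    for shift in range(1, 10):
        rotated = decompose_units(doubled, _block((shift, shift + 80), 10))
        assert rotated.n_units == base.n_units
        # same cyclic repeat class: every recovered unit is a rotation
        rot_class = {unit[i:] + unit[:i] for i in range(10)}
        assert set(rotated.units) <= rot_class


# ----------------------------------------------------- nucleotide_diversity

def brute_force_pi(units):
    """Independent all-pairs Hamming oracle."""
    vals = []
    for u1, u2 in itertools.combinations(units, 2):
        sites = diffs = 0
        for x, y in zip(u1, u2):
            if x == "N" or y == "N":
                continue
            sites += 1
            diffs += x != y
        vals.append(diffs / sites)
    return sum(vals) / len(vals)


def test_pi_worked_examples():
    assert nucleotide_diversity(["ACGT", "ACGT", "ACGT"]) == 0.0
    assert nucleotide_diversity(["ACGT", "ACGA", "ACGT"]) == pytest.approx(1 / 6)
    assert nucleotide_diversity(["AAAA", "TTTT"]) == 1.0
    with pytest.raises(ValueError):
        nucleotide_diversity(["ACGT"])


def test_pi_excludes_n_sites_pairwise():
    # pair (ACGN, ACGT): 3 comparable sites, 0 diffs; (ACGN, TCGT): 3
    # sites 1 diff; (ACGT, TCGT): 4 sites 1 diff
    units = ["ACGN", "ACGT", "TCGT"]
    expected = (0 + 1 / 3 + 1 / 4) / 3
    assert nucleotide_diversity(units) == pytest.approx(expected)


def test_pi_matches_brute_force_on_seeded_instances():
    rng = np.random.default_rng(404)
    for _ in range(300):
        n = int(rng.integers(2, 8))
        L = int(rng.integers(3, 30))
        units = ["".join(rng.choice(list("ACGTN"), size=L,
                                    p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                 for _ in range(n)]
        if any(all(x == "N" or y == "N" for x, y in zip(u1, u2))
               for u1, u2 in itertools.combinations(units, 2)):
            continue
        assert nucleotide_diversity(units) == pytest.approx(
            brute_force_pi(units))


def test_pi_for_unequal_lengths_uses_alignment():
    # NW edit distance ACGT vs ACG = 1; normalized by mean length 3.5
    assert nucleotide_diversity(["ACGT", "ACG"]) == pytest.approx(1 / 3.5)


def test_pi_concentrates_near_expectation():
    """Units mutated i.i.d. at per-site rate q have expected pairwise
    difference ~ 2q(1 - 4q/3 ...); just check the estimate is close."""
    rng = np.random.default_rng(11)
    ancestor = simgen._random_seq(rng, 60)
    q = 0.03
    units = [simgen._mutate(rng, ancestor, q) for _ in range(40)]
    pi = nucleotide_diversity(units)
    expected = 2 * q * (1 - q) + (q ** 2) * (2 / 3)
    assert pi == pytest.approx(expected, rel=0.35)


# ----------------------------------------------------------------- gc

def test_gc_content_examples():
    assert gc_content("GGCC") == 1.0
    assert gc_content("AATT") == 0.0
    assert gc_content("ACGT") == 0.5
    assert gc_content("ACGTN") == 0.5  # N excluded from the denominator
    with pytest.raises(ValueError):
        gc_content("NNNN")


def welch_by_hand(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


def test_gc_enrichment_identical_lists_null():
    t, p, direction = gc_enrichment_test([0.5, 0.5, 0.6], [0.5, 0.5, 0.6])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_gc_enrichment_detects_higher_vntr_gc():
    rng = np.random.default_rng(3)
    vntr = rng.normal(0.60, 0.03, size=50)
    orf = rng.normal(0.516, 0.03, size=50)
    t, p, direction = gc_enrichment_test(list(vntr), list(orf))
    assert p < 0.01
    assert direction == "higher"
    assert t == pytest.approx(welch_by_hand(vntr, orf), rel=1e-9)


def test_gc_enrichment_needs_two_values_per_sample():
    with pytest.raises(ValueError):
        gc_enrichment_test([0.5], [0.4, 0.6])


def test_gc_enrichment_degenerate_zero_variance():
    t, p, _ = gc_enrichment_test([0.5, 0.5], [0.5, 0.5])
    assert (t, p) == (0.0, 1.0)


# -------------------------------------------------------------- summarize

def _call_with(copies_a, copies_b, unit, strain, flagged=False):
    b = RepeatBlock("g1", (0, int(copies_a * unit)), (0, int(copies_b * unit)),
                    unit, copies_a, copies_b, copies_b / copies_a, 1.0, 9)
    return VntrCall(gene_id="g1", strain=strain, blocks=(b,), flagged=flagged,
                    reason="ratio_high" if flagged else "none")


def test_single_strain_summary_spans_reference():
    s = summarize_gene([_call_with(11, 25, 42, "cast", flagged=True)])
    assert s.copy_range == (11, 25)
    assert s.unit_len_range == (42, 42)
    assert s.strains_flagged == ("cast",)


def test_two_strain_summary():
    # one strain sees 8 copies, another 23, reference in between
    calls = [_call_with(12, 8, 228, "s1"), _call_with(12, 23, 228, "s2")]
    s = summarize_gene(calls)
    assert s.copy_range == (8, 23)
    assert s.unit_len_range == (228, 228)


def test_summary_absent_without_blocks():
    empty = VntrCall(gene_id="g1", strain="s", blocks=())
    assert summarize_gene([empty]) is None
    with pytest.raises(ValueError):
        summarize_gene([])
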