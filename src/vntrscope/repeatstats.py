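"""Repeat-unit decomposition and diversity statistics.

Detected blocks are decomposed into their tandem units, from which the
summary statistics of interest are computed: GC content, nucleotide
diversity pi (average pairwise per-site difference between units, no
finite-sample correction), the Welch t-test for GC enrichment of repeat
sequence over background coding sequence, and per-gene unit-length /
copy-number ranges across strains.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .anchors import encode
from .detector import RepeatBlock, VntrCall

__all__ = [
    "RepeatUnitSet",
    "VntrGeneSummary",
    "decompose_units",
    "nucleotide_diversity",
    "gc_content",
    "gc_enrichment_test",
    "summarize_gene",
]


@dataclass(frozen=True)
class RepeatUnitSet:
    gene_id: str
    strain: str
    units: tuple[str, ...]
    unit_len: int
    copies: float  # fractional copy count over the block span
    gc: float
    pi: float | None  # None when fewer than two units
    aligned: bool = False  # pi computed via pairwise alignment

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class VntrGeneSummary:
    gene_id: str
    unit_len_range: tuple[int, int]
    copy_range: tuple[float, float]
    strains_flagged: tuple[str, ...]


def _phase_identity(codes: np.ndarray, phase: int, unit: int) -> float:
    """Mean pairwise per-site identity of full units cut at this phase."""
    n_full = (len(codes) - phase) // unit
    if n_full < 2:
        return -1.0
    mat = codes[phase:phase + n_full * unit].reshape(n_full, unit)
    agree = 0
    for c in range(4):
        cnt = (mat == c).sum(axis=0)
        agree += int((cnt * (cnt - 1)).sum())
    pairs = n_full * (n_full - 1)
    return agree / (pairs * unit)


def decompose_units(seq: str, block: RepeatBlock, allele: str = "a",
                    strain: str = "") -> RepeatUnitSet:
    """Partition a block's sequence into repeat units of ``unit_len``.

    The cutting phase (0 .. unit_len-1) maximizing mean pairwise unit
    identity is chosen; ties go to the smallest phase.  Overhang bases at
    either end count toward the fractional copy number only where they
    continue the periodic pattern.
    """
    span = block.a_span if allele == "a" else block.b_span
    lo, hi = max(0, span[0]), min(len(seq), span[1])
    sub = seq[lo:hi]
    u = block.unit_len
    if u < 1 or len(sub) < u:
        raise ValueError(
            f"block span of {len(sub)} bp is shorter than one {u} bp unit")
    codes = encode(sub)
    best_phase, best_score = 0, -1.0
    for phase in range(min(u, max(1, len(sub) - u + 1))):
        score = _phase_identity(codes, phase, u)
        if score > best_score:
            best_phase, best_score = phase, score
    n_full = (len(sub) - best_phase) // u
    if n_full < 1:
        best_phase, n_full = 0, len(sub) // u
    units = tuple(sub[best_phase + i * u: best_phase + (i + 1) * u]
                  for i in range(n_full))
    copies = n_full + _periodic_overhang(codes, best_phase, n_full, u) / u
    gc = gc_content(sub)
    pi = nucleotide_diversity(list(units)) if len(units) >= 2 else None
    return RepeatUnitSet(gene_id=block.gene_id, strain=strain, units=units,
                         unit_len=u, copies=copies, gc=gc, pi=pi)


def _periodic_overhang(codes: np.ndarray, phase: int, n_full: int, u: int) -> int:
    """Overhang bases (either end) consistent with the periodic extension."""
    n = len(codes)
    extra = 0
    for i in range(phase):  # leading overhang, compared one period right
        if codes[i] >= 0 and codes[i] == codes[i + u]:
            extra += 1
    tail = phase + n_full * u
    for i in range(tail, n):  # trailing overhang, compared one period left
        if codes[i] >= 0 and codes[i] == codes[i - u]:
            extra += 1
    return extra


def nucleotide_diversity(units: list[str]) -> float:
    """Average pairwise per-site difference (pi) among repeat units.

    Equal-length units are compared site-by-site, excluding positions
    where either unit carries N from both numerator and denominator of
    that pair.  Unequal-length units are compared by global (NW) edit
    distance normalized by the mean of the two lengths.  Raises on fewer
    than two units.
    """
    if len(units) < 2:
        raise ValueError("pi is undefined for fewer than two units")
    lens = {len(x) for x in units}
    if len(lens) == 1:
        codes = [encode(x) for x in units]
        vals = []
        for c1, c2 in itertools.combinations(codes, 2):
            valid = (c1 >= 0) & (c2 >= 0)
            sites = int(valid.sum())
            if sites == 0:
                continue
            diffs = int(((c1 != c2) & valid).sum())
            vals.append(diffs / sites)
        return float(np.mean(vals)) if vals else 0.0
    import edlib

    vals = []
    for u1, u2 in itertools.combinations(units, 2):
        d = edlib.align(u1, u2, mode="NW", task="distance")["editDistance"]
        vals.append(d / ((len(u1) + len(u2)) / 2))
    return float(np.mean(vals))


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); bases outside ACGT are excluded."""
    if not seq:
        raise ValueError("gc_content of an empty sequence")
    codes = encode(seq)
    acgt = int((codes >= 0).sum())
    if acgt == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / acgt


def gc_enrichment_test(vntr_gc: list[float], background_gc: list[float]
                       ) -> tuple[float, float, str]:
    """Welch two-sample two-sided t-test of repeat GC vs background GC.

    Returns (t statistic, two-sided p, direction) where direction is
    "higher", "lower" or "equal" for the repeat-set mean relative to
    background.  Two zero-variance samples with equal means give t=0, p=1.
    """
    a = np.asarray(vntr_gc, dtype=float)
    b = np.asarray(background_gc, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "equal"
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        return 0.0, 1.0, "equal"
    da, db = a.mean(), b.mean()
    direction = "higher" if da > db else ("lower" if da < db else "equal")
    return float(t), float(p), direction


def summarize_gene(calls: list[VntrCall]) -> VntrGeneSummary | None:
    """Unit-length and copy-number ranges for one gene across strains.

    The reference allele participates as a pseudo-strain through each
    call's copies_a.  Returns None when no call carries a block.
    """
    if not calls:
        raise ValueError("summarize_gene needs at least one call")
    gene_ids = {c.gene_id for c in calls}
    if len(gene_ids) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(gene_ids)}")
    units: list[int] = []
    copies: list[float] = []
    flagged: list[str] = []
    for call in calls:
        for b in call.blocks:
            units.append(b.unit_len)
            copies.extend((b.copies_a, b.copies_b))
        if call.flagged:
            flagged.append(call.strain)
    if not units:
        return None
    return VntrGeneSummary(
        gene_id=gene_ids.pop(),
        unit_len_range=(min(units), max(units)),
        copy_range=(min(copies), max(copies)),
        strains_flagged=tuple(sorted(set(flagged))),
    )
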