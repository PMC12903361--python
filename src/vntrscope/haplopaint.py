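"""Haplotype mosaic painting for MHC-like loci.

A query haplotype is sliced into 100 kb fragments, each fragment is
anchored onto every donor haplotype, and substitutions are counted per
non-overlapping 10 kb window.  A window qualifies for a donor when it
carries fewer than ``max_snps_per_window`` substitutions (default 3, i.e.
0.3 per mille) and is labeled with the highest-ranking qualifying donor
under a fixed hierarchy; windows qualifying for no donor keep the query's
own label.  Adjacent same-label windows merge into segments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anchors import AnchorParams, encode, find_anchors

__all__ = [
    "PaintConfig",
    "HaplotypeSegment",
    "UNALIGNED",
    "slice_haplotype",
    "window_snp_counts",
    "paint_windows",
    "paint_haplotype",
]

#: Sentinel count for windows with insufficient anchored coverage; never
#: qualifies for any donor.
UNALIGNED = math.inf

# Default precedence among mouse H2 haplotype labels, highest first.
DEFAULT_HIERARCHY = ("b", "k", "d", "a", "q", "c", "g", "z")


class PaintConfigError(ValueError):
    """Raised for inconsistent painting configuration or donor labels."""


@dataclass(frozen=True)
class PaintConfig:
    slice_len: int = 100_000
    window_len: int = 10_000
    max_snps_per_window: int = 3  # strict: a window qualifies iff count < this
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    min_window_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.slice_len % self.window_len != 0:
            raise PaintConfigError("slice_len must be a multiple of window_len")
        if len(set(self.hierarchy)) != len(self.hierarchy):
            raise PaintConfigError("hierarchy labels must be unique")


@dataclass(frozen=True)
class HaplotypeSegment:
    """A painted run of windows with one assigned donor label (or self)."""

    query_label: str
    start: int  # query offsets, 0-based half-open
    end: int
    assigned: str
    snp_counts: dict[str, int] = field(default_factory=dict)


def slice_haplotype(seq: str, cfg: PaintConfig | None = None
                    ) -> list[tuple[int, str]]:
    """Cut a haplotype into consecutive ``slice_len`` fragments.

    A final short fragment is kept on its own when it is at least one
    window long, otherwise appended to the previous fragment.  A sequence
    shorter than one window raises.
    """
    cfg = cfg or PaintConfig()
    if len(seq) < cfg.window_len:
        raise ValueError(
            f"sequence of {len(seq)} bp is shorter than one "
            f"{cfg.window_len} bp window")
    frags: list[tuple[int, str]] = []
    pos = 0
    while pos < len(seq):
        frags.append((pos, seq[pos:pos + cfg.slice_len]))
        pos += cfg.slice_len
    if len(frags) > 1 and len(frags[-1][1]) < cfg.window_len:
        off, tail = frags.pop()
        prev_off, prev = frags.pop()
        frags.append((prev_off, prev + tail))
    return frags


def _window_grid(n: int, window_len: int) -> list[tuple[int, int]]:
    bounds = list(range(0, n, window_len)) + [n]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def window_snp_counts(fragment: str, donor: str,
                      cfg: PaintConfig | None = None,
                      params: AnchorParams | None = None) -> np.ndarray:
    """Per-window substitution counts of a fragment against one donor.

    The fragment is anchored to the donor (ungapped anchors, best-scoring
    first); each fragment position is counted at most once, under the
    anchor that reaches it first.  Windows with less than
    ``min_window_coverage`` anchored coverage get the UNALIGNED sentinel.
    Indels are not counted — substitutions only.
    """
    cfg = cfg or PaintConfig()
    params = params or AnchorParams()
    n = len(fragment)
    grid = _window_grid(n, cfg.window_len)
    counts = np.zeros(len(grid))
    if not donor:
        counts[:] = UNALIGNED
        return counts
    cf = encode(fragment)
    cd = encode(donor)
    anchors = sorted(find_anchors(cf, cd, params),
                     key=lambda s: (-s.score, s.a_start, s.diag))
    covered = np.zeros(n, dtype=bool)
    mismatch = np.zeros(n, dtype=bool)
    for s in anchors:
        region = slice(s.a_start, s.a_end)
        new = ~covered[region]
        if not new.any():
            continue
        frag_part = cf[region]
        donor_part = cd[s.b_start:s.b_end]
        mm = (frag_part != donor_part) & (frag_part >= 0) & (donor_part >= 0)
        mismatch[region] |= mm & new
        covered[region] = True
    for w, (lo, hi) in enumerate(grid):
        cov = covered[lo:hi].mean()
        if cov < cfg.min_window_coverage:
            counts[w] = UNALIGNED
        else:
            counts[w] = int(mismatch[lo:hi].sum())
    return counts


def paint_windows(counts: dict[str, np.ndarray],
                  cfg: PaintConfig | None = None,
                  query_label: str = "self",
                  offset: int = 0,
                  fragment_len: int | None = None) -> list[HaplotypeSegment]:
    """Label windows by the highest-hierarchy donor with < max SNPs.

    ``counts`` maps donor label to the per-window substitution counts of
    one fragment (shared grid).  Only donors ranked above the query in the
    hierarchy can capture a window; windows qualifying for none keep the
    query's own label.  Adjacent same-label windows merge.
    """
    cfg = cfg or PaintConfig()
    rank = {lab: i for i, lab in enumerate(cfg.hierarchy)}
    for lab in counts:
        if lab not in rank:
            raise PaintConfigError(
                f"donor label {lab!r} is not in the hierarchy {cfg.hierarchy}")
    query_rank = rank.get(query_label, len(cfg.hierarchy))
    eligible = [lab for lab in cfg.hierarchy
                if lab in counts and rank[lab] < query_rank]
    lengths = {len(v) for v in counts.values()}
    if len(lengths) > 1:
        raise PaintConfigError("donors disagree on the window grid")
    n_win = lengths.pop() if lengths else 0
    if fragment_len is None:
        fragment_len = n_win * cfg.window_len

    segments: list[HaplotypeSegment] = []
    for w in range(n_win):
        assigned = query_label
        for lab in eligible:  # hierarchy order, highest first
            if counts[lab][w] < cfg.max_snps_per_window:
                assigned = lab
                break
        w_start = offset + w * cfg.window_len
        w_end = offset + min((w + 1) * cfg.window_len, fragment_len)
        win_counts = {lab: int(counts[lab][w]) for lab in counts
                      if math.isfinite(counts[lab][w])}
        if segments and segments[-1].assigned == assigned \
                and segments[-1].end == w_start:
            prev = segments.pop()
            merged = dict(prev.snp_counts)
            for lab, v in win_counts.items():
                merged[lab] = max(merged.get(lab, 0), v)
            segments.append(HaplotypeSegment(
                query_label=query_label, start=prev.start, end=w_end,
                assigned=assigned, snp_counts=merged))
        else:
            segments.append(HaplotypeSegment(
                query_label=query_label, start=w_start, end=w_end,
                assigned=assigned, snp_counts=win_counts))
    return segments


def paint_haplotype(query: str, donors: dict[str, str],
                    cfg: PaintConfig | None = None,
                    query_label: str = "self",
                    params: AnchorParams | None = None
                    ) -> list[HaplotypeSegment]:
    """Slice, count and paint a whole query haplotype against a donor panel."""
    cfg = cfg or PaintConfig()
    segments: list[HaplotypeSegment] = []
    for offset, fragment in slice_haplotype(query, cfg):
        counts = {}
        for lab, donor_seq in donors.items():
            if lab == query_label:
                continue
            counts[lab] = window_snp_counts(fragment, donor_seq, cfg, params)
        segs = paint_windows(counts, cfg, query_label=query_label,
                             offset=offset, fragment_len=len(fragment))
        for seg in segs:
            if segments and segments[-1].assigned == seg.assigned \
                    and segments[-1].end == seg.start:
                prev = segments.pop()
                merged = dict(prev.snp_counts)
                for lab, v in seg.snp_counts.items():
                    merged[lab] = max(merged.get(lab, 0), v)
                segments.append(HaplotypeSegment(
                    query_label=query_label, start=prev.start, end=seg.end,
                    assigned=seg.assigned, snp_counts=merged))
            else:
                segments.append(seg)
    return segments
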