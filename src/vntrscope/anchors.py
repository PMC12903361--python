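"""Dot-plot primitives: ungapped anchor segments and fixed-size rasterization.

A dot plot between two sequences is, geometrically, the set of ungapped
local matches ("anchors") between them.  Tandem repeats show up as families
of lines parallel to the main diagonal, spaced by the repeat-unit length.
This module finds those anchors by exact-seed lookup followed by X-drop
style ungapped extension, and can rasterize them to the fixed 750x750 pixel
grid used for visual inspection (830x830 with axis margins).

Detection downstream operates on the exact sequence-space geometry; the
raster exists for visualization and for plugging in any external
image-based detector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "AnchorParams",
    "AnchorSegment",
    "RasterGrid",
    "encode",
    "find_anchors",
    "rasterize",
]

# Nucleotide -> code; anything not A/C/G/T (including N and ambiguity codes)
# maps to -1 and can neither seed nor match.
_CODES = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"ACGT"):
    _CODES[_c] = _i
    _CODES[_c + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


@dataclass(frozen=True)
class AnchorParams:
    """Scoring parameters for seed-and-extend anchor finding.

    Defaults follow the match/mismatch scores, X-drop and score cutoff of
    the yass invocation the pipeline emulates (+5 match, -4 mismatch,
    X-drop 30, minimum segment score 70), with exact 12-mer seeds and a
    70% identity floor.
    """

    seed_len: int = 12
    match_score: int = 5
    mismatch_score: int = -4
    xdrop: int = 30
    min_anchor_score: int = 70
    min_identity: float = 0.7

    def __post_init__(self) -> None:
        if self.seed_len < 4:
            raise ValueError("seed_len must be >= 4")
        if self.min_anchor_score <= 0:
            raise ValueError("min_anchor_score must be positive")
        if self.mismatch_score >= 0 or self.match_score <= 0:
            raise ValueError("match_score > 0 > mismatch_score required")

    @property
    def max_gap(self) -> int:
        # Longest run of consecutive mismatches an X-drop extension survives.
        return (self.xdrop - 1) // (-self.mismatch_score)


@dataclass(frozen=True)
class AnchorSegment:
    """An ungapped local match between sequence A and sequence B.

    Coordinates are 0-based half-open; the segment occupies the single
    diagonal ``diag = b_start - a_start``.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    score: int
    identity: float

    @property
    def diag(self) -> int:
        return self.b_start - self.a_start

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def transposed(self) -> "AnchorSegment":
        return AnchorSegment(
            self.b_start, self.b_end, self.a_start, self.a_end,
            self.matches, self.score, self.identity,
        )


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer k-mer code per position; -1 where the window contains non-ACGT."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    base = np.where(valid, codes, 0).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    km = sliding_window_view(base, k) @ weights
    ok = sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, km, -1)


def _candidate_diagonals(codes_a: np.ndarray, codes_b: np.ndarray, k: int
                         ) -> dict[int, tuple[int, int]]:
    """Diagonals (b_pos - a_pos) carrying at least one shared exact k-mer,
    mapped to the (min, max) a-position of their seed hits."""
    ka = _kmer_codes(codes_a, k)
    kb = _kmer_codes(codes_b, k)
    pa = np.flatnonzero(ka >= 0)
    pb = np.flatnonzero(kb >= 0)
    if len(pa) == 0 or len(pb) == 0:
        return {}
    va, vb = ka[pa], kb[pb]
    ob = np.argsort(vb, kind="stable")
    vb_s, pb_s = vb[ob], pb[ob].astype(np.int64)
    lo = np.searchsorted(vb_s, va)
    hi = np.searchsorted(vb_s, va, side="right")
    cnt = (hi - lo).astype(np.int64)
    keep = cnt > 0
    pa_k, lo_k, cnt_k = pa[keep].astype(np.int64), lo[keep], cnt[keep]
    windows: dict[int, tuple[int, int]] = {}
    # Expand all (a_pos, b_pos) seed pairs in blocks of bounded size.
    cum = np.concatenate(([0], np.cumsum(cnt_k)))
    block = 8_000_000
    start_row = 0
    while start_row < len(pa_k):
        end_row = start_row
        while end_row < len(pa_k) and \
                cum[end_row + 1] - cum[start_row] <= block:
            end_row += 1
        end_row = max(end_row, start_row + 1)
        c = cnt_k[start_row:end_row]
        n_pairs = int(c.sum())
        out_a = np.repeat(pa_k[start_row:end_row], c)
        offsets = np.arange(n_pairs) - np.repeat(
            (cum[start_row:end_row] - cum[start_row]), c)
        out_b = pb_s[np.repeat(lo_k[start_row:end_row], c) + offsets]
        dg = out_b - out_a
        uniq, inv = np.unique(dg, return_inverse=True)
        mins = np.full(len(uniq), np.iinfo(np.int64).max)
        maxs = np.full(len(uniq), np.iinfo(np.int64).min)
        np.minimum.at(mins, inv, out_a)
        np.maximum.at(maxs, inv, out_a)
        for d, mn, mx in zip(uniq.tolist(), mins.tolist(), maxs.tolist()):
            old = windows.get(d)
            if old is None:
                windows[d] = (mn, mx)
            else:
                windows[d] = (min(old[0], mn), max(old[1], mx))
        start_row = end_row
    return windows


def _best_window(mlen: np.ndarray, gaps: np.ndarray, p: AnchorParams):
    """Maximal-scoring contiguous run window (Kadane over run/gap weights).

    Returns (score, i, j) for runs[i..j]; windows start and end on match
    runs so the segment is never mismatch-terminated.
    """
    ms, gs = p.match_score, p.mismatch_score
    n = len(mlen)
    best = (-1, 0, -1)
    prefix_min = 0  # min over i of P_i
    prefix_min_idx = 0
    P = 0  # P_j = sum over t<j of (ms*mlen[t] + gs*gaps[t])
    for j in range(n):
        end_val = P + ms * int(mlen[j])  # window score ending at run j, start at prefix_min_idx
        score = end_val - prefix_min
        if score > best[0]:
            best = (score, prefix_min_idx, j)
        P = end_val + gs * int(gaps[j])
        if P < prefix_min:
            prefix_min = P
            prefix_min_idx = j + 1
    return best


_SEED_MARGIN = 2000  # scan margin around seed hits on a diagonal


def _segments_on_diagonal(codes_a, codes_b, d: int, p: AnchorParams,
                          out: list[AnchorSegment],
                          seed_window: tuple[int, int] | None = None) -> None:
    a_lo = max(0, -d)
    a_hi = min(len(codes_a), len(codes_b) - d)
    if seed_window is not None:
        # An anchor of acceptable identity essentially always contains an
        # exact seed-length run near every few hundred bases, so scanning
        # far outside the seeded region cannot lose qualifying segments.
        a_lo = max(a_lo, seed_window[0] - _SEED_MARGIN)
        a_hi = min(a_hi, seed_window[1] + p.seed_len + _SEED_MARGIN)
    if a_hi - a_lo < p.seed_len:
        return
    sa = codes_a[a_lo:a_hi]
    sb = codes_b[a_lo + d:a_hi + d]
    m = (sa == sb) & (sa >= 0)
    if not m.any():
        return
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.astype(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]
    run_len = ends - starts
    # Chain runs whose inter-run mismatch gap an X-drop extension can cross.
    gap_after = np.empty(len(starts), dtype=np.int64)
    gap_after[:-1] = starts[1:] - ends[:-1]
    gap_after[-1] = 0
    chain_break = np.flatnonzero(gap_after[:-1] > p.max_gap) + 1
    bounds = np.concatenate(([0], chain_break, [len(starts)]))
    # A chain without a single seed-length exact run can never yield an
    # anchor (the seed filter would discard every window); skip cheaply.
    n_chains = len(bounds) - 1
    chain_id = np.zeros(len(starts), dtype=np.int64)
    if len(chain_break):
        chain_id[chain_break] = 1
        chain_id = np.cumsum(chain_id)
    chain_max = np.zeros(n_chains, dtype=np.int64)
    np.maximum.at(chain_max, chain_id, run_len)
    for c in np.flatnonzero(chain_max >= p.seed_len):
        lo, hi = bounds[c], bounds[c + 1]
        _extract_from_chain(starts[lo:hi], ends[lo:hi], run_len[lo:hi],
                            gap_after[lo:hi], d, a_lo, p, out)


def _extract_from_chain(starts, ends, run_len, gap_after, d, a_lo, p, out) -> None:
    """Recursively peel maximal-scoring sub-segments out of one run chain."""
    stack = [(0, len(starts))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        gaps = gap_after[lo:hi].copy()
        gaps[-1] = 0
        score, i, j = _best_window(run_len[lo:hi], gaps, p)
        if score < p.min_anchor_score:
            continue
        i += lo
        j += lo
        seg_start = int(starts[i])
        seg_end = int(ends[j])
        matches = int(run_len[i:j + 1].sum())
        length = seg_end - seg_start
        identity = matches / length
        max_run = int(run_len[i:j + 1].max())
        if identity >= p.min_identity and max_run >= p.seed_len:
            out.append(AnchorSegment(
                a_start=a_lo + seg_start,
                a_end=a_lo + seg_end,
                b_start=a_lo + seg_start + d,
                b_end=a_lo + seg_end + d,
                matches=matches,
                score=score,
                identity=identity,
            ))
        stack.append((lo, i))
        stack.append((j + 1, hi))


def find_anchors(seq_a, seq_b, params: AnchorParams | None = None) -> list[AnchorSegment]:
    """All ungapped anchor segments between two sequences (forward strand).

    ``seq_a``/``seq_b`` may be strings or pre-encoded int8 arrays.  Every
    returned segment contains at least one exact run of ``seed_len``
    matches, scores at least ``min_anchor_score`` under the +5/-4 scheme,
    and has identity >= ``min_identity``.  N bases never seed or match.
    Output is sorted by (diag, a_start) and deterministic.
    """
    p = params or AnchorParams()
    ca = seq_a if isinstance(seq_a, np.ndarray) else encode(seq_a)
    cb = seq_b if isinstance(seq_b, np.ndarray) else encode(seq_b)
    if len(ca) < p.seed_len or len(cb) < p.seed_len:
        return []
    out: list[AnchorSegment] = []
    windows = _candidate_diagonals(ca, cb, p.seed_len)
    for d in sorted(windows):
        _segments_on_diagonal(ca, cb, int(d), p, out, windows[d])
    out.sort(key=lambda s: (s.diag, s.a_start))
    return out


@dataclass
class RasterGrid:
    """Fixed-size occupancy raster of a dot plot (750x750 plot area)."""

    width: int
    height: int
    scale_a: float
    scale_b: float
    cells: np.ndarray = field(repr=False)


def rasterize(anchors: list[AnchorSegment], len_a: int, len_b: int,
              width: int = 750, height: int = 750) -> RasterGrid:
    """Draw anchors as lines on a fixed-size pixel grid.

    The grid dimensions are independent of sequence length; ``scale_a`` and
    ``scale_b`` give bases per pixel.  ``cells[y, x]`` counts the anchors
    touching the cell (x along sequence A, y along sequence B).
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("rasterize requires positive sequence lengths")
    scale_a = len_a / width
    scale_b = len_b / height
    cells = np.zeros((height, width), dtype=np.int32)
    for s in anchors:
        x0 = s.a_start / scale_a
        x1 = (s.a_end - 1) / scale_a
        y0 = s.b_start / scale_b
        y1 = (s.b_end - 1) / scale_b
        n = int(max(abs(x1 - x0), abs(y1 - y0))) + 1
        xs = np.clip(np.linspace(x0, x1, n).astype(np.int64), 0, width - 1)
        ys = np.clip(np.linspace(y0, y1, n).astype(np.int64), 0, height - 1)
        flat = np.unique(ys * width + xs)
        cells.ravel()[flat] += 1
    return RasterGrid(width=width, height=height, scale_a=scale_a,
                      scale_b=scale_b, cells=cells)


def grid_to_image(grid: RasterGrid, axis_margin: int = 40):
    """Export the raster as a PIL image with axis margins (830x830 at defaults)."""
    from PIL import Image

    h = grid.height + 2 * axis_margin
    w = grid.width + 2 * axis_margin
    canvas = np.full((h, w), 255, dtype=np.uint8)
    plot = np.where(grid.cells > 0, 0, 255).astype(np.uint8)
    canvas[axis_margin:axis_margin + grid.height,
           axis_margin:axis_margin + grid.width] = plot
    # simple axis frame
    m = axis_margin - 1
    canvas[m, m:w - m] = 0
    canvas[h - m - 1, m:w - m] = 0
    canvas[m:h - m, m] = 0
    canvas[m:h - m, w - m - 1] = 0
    return Image.fromarray(canvas, mode="L")
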