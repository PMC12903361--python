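"""CDS pre-processing: fixed-window chunking with symmetric N padding.

Coding sequences shorter than the comparison window (10 kb by default) are
padded with equal runs of N on both ends; longer sequences are split into
consecutive full windows, with a trailing fragment of at least ``min_tail``
bases (100 bp by default) centre-padded into a final window and shorter
tails dropped.  Padding keeps every compared window the same physical size
so dot plots share a scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

__all__ = ["Chunk", "chunk_cds"]


@dataclass(frozen=True)
class Chunk:
    source_gene: str
    index: int
    core_start: int  # offsets into the original CDS, 0-based half-open
    core_end: int
    seq: str  # fixed window length, N-padded
    left_pad: int
    right_pad: int

    @property
    def core_len(self) -> int:
        return self.core_end - self.core_start


def _padded(seq: str, start: int, end: int, window: int, index: int,
            source_gene: str) -> Chunk:
    core = seq[start:end]
    pad = window - len(core)
    left = pad // 2
    right = pad - left  # odd remainder goes to the right end
    return Chunk(source_gene=source_gene, index=index, core_start=start,
                 core_end=end, seq="N" * left + core + "N" * right,
                 left_pad=left, right_pad=right)


def chunk_cds(seq: str, window: int = 10_000, min_tail: int = 100,
              source_gene: str = "") -> list[Chunk]:
    """Split or pad a CDS into fixed-length windows.

    A CDS shorter than ``window`` yields one centre-padded chunk.  A longer
    CDS yields consecutive exact windows; a trailing fragment in
    ``[min_tail, window)`` becomes a final centre-padded chunk and a
    shorter tail is dropped (logged).
    """
    if not seq:
        raise ValueError("cannot chunk an empty sequence")
    if not (window >= min_tail >= 1):
        raise ValueError("require window >= min_tail >= 1")
    n = len(seq)
    if n < window:
        return [_padded(seq, 0, n, window, 0, source_gene)]
    chunks = []
    full = n // window
    for i in range(full):
        start = i * window
        chunks.append(Chunk(source_gene=source_gene, index=i,
                            core_start=start, core_end=start + window,
                            seq=seq[start:start + window],
                            left_pad=0, right_pad=0))
    rem = n - full * window
    if rem >= min_tail:
        chunks.append(_padded(seq, full * window, n, window, full, source_gene))
    elif rem > 0:
        log.info("dropped %d bp tail of %s (< min_tail %d)",
                 rem, source_gene or "<cds>", min_tail)
    return chunks
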