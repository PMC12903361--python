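"""Sequence and annotation I/O: FASTA, GFF3 CDS extraction, ortholog pairing,
and the TSV/BED writers for scan results.

All internal coordinates are 0-based half-open; conversion happens only at
the GFF3 boundary (1-based inclusive) and is a no-op for BED.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "FormatError",
    "CdsRecord",
    "OrthologPair",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "extract_cds",
    "pair_orthologs",
    "write_outputs",
    "read_bed",
]

# IUPAC nucleotide codes (upper case after folding)
_IUPAC = set("ACGTRYSWKMBDHVN")

_COMPL = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """Raised for malformed input files."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence map.

    IDs are the first whitespace-delimited token of the header.  Duplicate
    IDs or non-IUPAC characters raise :class:`FormatError` naming the
    offending record; an empty file yields an empty map.
    """
    path = Path(path)
    records: dict[str, str] = {}
    n = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path} is not FASTA: {exc}") from exc
    for rec in parsed:
        n += 1
        seq = str(rec.seq).upper()
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"record {rec.id!r} in {path} contains non-IUPAC "
                f"characters {sorted(bad)!r}")
        records[rec.id] = seq
    if n == 0 and path.read_text().strip():
        raise FormatError(f"{path} is not FASTA (no records parsed)")
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class CdsRecord:
    """A spliced, strand-resolved coding sequence with provenance coordinates.

    ``exon_intervals`` are 0-based half-open genome coordinates sorted by
    genome position; ``seq`` is the spliced CDS, already reverse-
    complemented for minus-strand records.
    """

    gene_id: str
    transcript_id: str
    strain: str
    chrom: str
    exon_intervals: tuple[tuple[int, int], ...]
    strand: str
    seq: str

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.exon_intervals)
        if total != len(self.seq):
            raise ValueError(
                f"{self.transcript_id}: spliced length {len(self.seq)} != "
                f"sum of exon intervals {total}")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class OrthologPair:
    gene_id: str
    ref_cds: CdsRecord
    strain_cds: CdsRecord


def extract_cds(genome: dict[str, str], annotation, strain: str = "") -> list[CdsRecord]:
    """Extract spliced CDS records from a genome and a GFF3 annotation.

    Per transcript, CDS segments are concatenated in translation order
    (minus-strand transcripts are reverse-complemented).  A CDS feature on
    a chromosome absent from ``genome`` or a transcript with mixed strands
    raises :class:`FormatError`.
    """
    import gffutils

    db = gffutils.create_db(str(annotation), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id or "cds"]
        for parent in parents:
            groups.setdefault(parent, []).append(cds)

    out: list[CdsRecord] = []
    for tid, feats in groups.items():
        chroms = {f.seqid for f in feats}
        if len(chroms) > 1:
            raise FormatError(f"transcript {tid} spans multiple chromosomes")
        chrom = chroms.pop()
        if chrom not in genome:
            raise FormatError(
                f"CDS of transcript {tid} references missing chromosome {chrom!r}")
        strands = {f.strand for f in feats}
        if len(strands) > 1:
            raise FormatError(f"transcript {tid} has CDS on mixed strands")
        strand = strands.pop()
        if strand not in "+-":
            raise FormatError(f"transcript {tid} has no usable strand")
        feats = sorted(feats, key=lambda f: f.start)
        intervals = []
        prev_end = -1
        for f in feats:
            s, e = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
            if e <= s:
                raise FormatError(f"transcript {tid}: zero-length CDS segment")
            if s < prev_end:
                raise FormatError(f"transcript {tid}: overlapping CDS segments")
            prev_end = e
            intervals.append((s, e))
        spliced = "".join(genome[chrom][s:e] for s, e in intervals)
        if not spliced:
            raise FormatError(f"transcript {tid}: CDS of length 0")
        if strand == "-":
            spliced = revcomp(spliced)
        gene_id = _resolve_gene_id(db, tid, feats)
        out.append(CdsRecord(gene_id=gene_id, transcript_id=tid, strain=strain,
                             chrom=chrom, exon_intervals=tuple(intervals),
                             strand=strand, seq=spliced.upper()))
    out.sort(key=lambda r: (r.gene_id, r.transcript_id))
    return out


def _resolve_gene_id(db, tid: str, feats) -> str:
    try:
        parent = db[tid]
        gp = parent.attributes.get("Parent")
        if gp:
            return gp[0]
        gid = parent.attributes.get("gene_id")
        if gid:
            return gid[0]
    except Exception:
        pass
    for f in feats:
        gid = f.attributes.get("gene_id")
        if gid:
            return gid[0]
    return tid


def pair_orthologs(ref: list[CdsRecord], strain: list[CdsRecord]
                   ) -> tuple[list[OrthologPair], dict[str, str]]:
    """Pair reference and strain CDS records by shared gene_id.

    One canonical transcript per gene per side: the longest CDS, ties
    broken lexicographically by transcript_id.  Genes present on only one
    side go to the skipped map (gene_id -> reason) instead of raising.
    """

    def canonical(records: list[CdsRecord]) -> dict[str, CdsRecord]:
        by_gene: dict[str, CdsRecord] = {}
        for rec in sorted(records, key=lambda r: (-len(r.seq), r.transcript_id)):
            by_gene.setdefault(rec.gene_id, rec)
        return by_gene

    ref_by = canonical(ref)
    strain_by = canonical(strain)
    pairs: list[OrthologPair] = []
    skipped: dict[str, str] = {}
    for gid in sorted(set(ref_by) | set(strain_by)):
        if gid not in strain_by:
            skipped[gid] = "missing_in_strain"
        elif gid not in ref_by:
            skipped[gid] = "missing_in_ref"
        else:
            r, s = ref_by[gid], strain_by[gid]
            if not r.seq or not s.seq:
                skipped[gid] = "empty_cds"
            else:
                pairs.append(OrthologPair(gene_id=gid, ref_cds=r, strain_cds=s))
    return pairs, skipped


CALL_COLUMNS = ("gene", "strain", "unit_len", "copies_ref", "copies_strain",
                "r", "confidence", "flagged", "reason")


def write_outputs(calls, blocks, paint, out_dir) -> dict[str, Path]:
    """Write the scan's tabular outputs.

    ``calls`` rows go to ``vntr_calls.tsv`` (one row per gene x strain,
    representative block = highest confidence).  ``blocks`` go to BED6
    files in reference-allele and strain-allele coordinates; painted
    segments go to ``painting.bed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out_dir / "vntr_calls.tsv",
        "blocks_ref": out_dir / "blocks_ref.bed",
        "blocks_strain": out_dir / "blocks_strain.bed",
        "paint": out_dir / "painting.bed",
    }
    with open(paths["calls"], "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for call in calls:
            if call.blocks:
                top = max(call.blocks, key=lambda b: (b.confidence,
                                                      b.copies_a + b.copies_b))
                row = (call.gene_id, call.strain, str(top.unit_len),
                       f"{top.copies_a:.2f}", f"{top.copies_b:.2f}",
                       f"{top.r:.4f}", f"{top.confidence:.4f}",
                       str(int(call.flagged)), call.reason)
            else:
                row = (call.gene_id, call.strain, "NA", "NA", "NA", "NA",
                       "NA", "0", "none")
            fh.write("\t".join(row) + "\n")

    def bed_score(x: float) -> int:
        return max(0, min(1000, int(round(x * 1000))))

    with open(paths["blocks_ref"], "w") as ref_fh, \
            open(paths["blocks_strain"], "w") as strain_fh:
        for b in blocks:
            name = f"unit{b.unit_len}"
            score = bed_score(b.confidence)
            ref_fh.write(f"{b.gene_id}\t{b.a_span[0]}\t{b.a_span[1]}\t"
                         f"{name}\t{score}\t+\n")
            strain_fh.write(f"{b.gene_id}\t{b.b_span[0]}\t{b.b_span[1]}\t"
                            f"{name}\t{score}\t+\n")

    with open(paths["paint"], "w") as fh:
        for seg in paint:
            counts = [c for c in seg.snp_counts.values()]
            score = max(0, min(1000, max(counts) if counts else 0))
            fh.write(f"{seg.query_label}\t{seg.start}\t{seg.end}\t"
                     f"{seg.assigned}\t{score}\t+\n")
    return paths


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    """Parse a BED6 file back into tuples (round-trip helper)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3], int(parts[4]), parts[5]))
    return rows
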