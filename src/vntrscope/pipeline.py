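"""End-to-end VNTR scan: extract -> chunk -> anchors -> detect -> flag -> report."""
from __future__ import annotations

import logging
from pathlib import Path

from . import repeatstats, seqio
from .anchors import AnchorSegment, find_anchors
from .chunker import chunk_cds
from .config import ScanConfig
from .detector import VntrCall, detect_blocks, flag_polymorphic

log = logging.getLogger("vntrscope")

__all__ = ["ScanError", "scan_pair", "run_scan"]


class ScanError(RuntimeError):
    """A stage failure; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def pair_anchors(seq_a: str, seq_b: str, cfg: ScanConfig) -> list[AnchorSegment]:
    """Anchors between two whole CDS, computed per chunk pair and mapped
    back to whole-CDS coordinates (N padding stripped)."""
    params = cfg.anchor_params()
    chunks_a = chunk_cds(seq_a, cfg.chunk_window, cfg.chunk_min_tail)
    chunks_b = chunk_cds(seq_b, cfg.chunk_window, cfg.chunk_min_tail)
    anchors: list[AnchorSegment] = []
    for ca in chunks_a:
        off_a = ca.core_start - ca.left_pad
        for cb in chunks_b:
            off_b = cb.core_start - cb.left_pad
            for s in find_anchors(ca.seq, cb.seq, params):
                anchors.append(AnchorSegment(
                    a_start=s.a_start + off_a, a_end=s.a_end + off_a,
                    b_start=s.b_start + off_b, b_end=s.b_end + off_b,
                    matches=s.matches, score=s.score, identity=s.identity))
    anchors.sort(key=lambda s: (s.diag, s.a_start))
    return anchors


def scan_pair(pair: seqio.OrthologPair, cfg: ScanConfig) -> VntrCall:
    """Run chunking, anchor finding, detection and flagging on one pair."""
    seq_a = pair.ref_cds.seq
    seq_b = pair.strain_cds.seq
    anchors = pair_anchors(seq_a, seq_b, cfg)
    blocks = detect_blocks(anchors, len(seq_a), len(seq_b),
                           cfg.detector_config(), gene_id=pair.gene_id)
    call = VntrCall(gene_id=pair.gene_id, strain=pair.strain_cds.strain,
                    blocks=tuple(blocks))
    return flag_polymorphic([call], cfg.detector_config())[0]


def run_scan(ref_fasta, ref_gff, strain_fasta, strain_gff,
             strain_name: str, out_dir, cfg: ScanConfig | None = None) -> dict:
    """Scan every ortholog pair of a genome pair and write ranked reports.

    Outputs (TSV calls ranked by confidence descending, BED blocks per
    allele, per-unit repeat statistics, skipped genes) are written
    atomically: nothing is left behind if a stage fails.
    """
    cfg = cfg or ScanConfig()
    for label, path in (("ref_fasta", ref_fasta), ("ref_gff", ref_gff),
                        ("strain_fasta", strain_fasta),
                        ("strain_gff", strain_gff)):
        if not Path(path).exists():
            raise ScanError("inputs", f"missing {label} file: {path}")
    try:
        ref_genome = seqio.read_fasta(ref_fasta)
        strain_genome = seqio.read_fasta(strain_fasta)
        ref_cds = seqio.extract_cds(ref_genome, ref_gff, strain="ref")
        strain_cds = seqio.extract_cds(strain_genome, strain_gff,
                                       strain=strain_name)
    except seqio.FormatError as exc:
        raise ScanError("extract", str(exc)) from exc
    pairs, skipped = seqio.pair_orthologs(ref_cds, strain_cds)
    log.info("extracted %d ref / %d strain CDS; %d pairs, %d skipped",
             len(ref_cds), len(strain_cds), len(pairs), len(skipped))

    calls = []
    all_blocks = []
    stats_rows = []
    for pair in pairs:
        call = scan_pair(pair, cfg)
        if cfg.verbose:
            log.info("gene %s: %d blocks, flagged=%s", pair.gene_id,
                     len(call.blocks), call.flagged)
        calls.append(call)
        all_blocks.extend(call.blocks)
        for block in call.blocks:
            try:
                units = repeatstats.decompose_units(
                    pair.strain_cds.seq, block, allele="b",
                    strain=pair.strain_cds.strain)
            except ValueError:
                continue
            stats_rows.append({
                "gene": pair.gene_id, "strain": pair.strain_cds.strain,
                "unit_len": units.unit_len, "n_units": units.n_units,
                "copies": round(units.copies, 2), "gc": round(units.gc, 4),
                "pi": round(units.pi, 6) if units.pi is not None else "NA"})

    # rank by confidence descending, ties by gene_id
    def call_conf(c: VntrCall) -> float:
        return max((b.confidence for b in c.blocks), default=0.0)

    calls.sort(key=lambda c: (-call_conf(c), c.gene_id))
    all_blocks.sort(key=lambda b: (-b.confidence, b.gene_id, b.a_span))

    out_dir = Path(out_dir)
    try:
        paths = seqio.write_outputs(calls, all_blocks, [], out_dir)
        skipped_path = out_dir / "skipped_genes.tsv"
        with open(skipped_path, "w") as fh:
            fh.write("gene\treason\n")
            for gid, reason in sorted(skipped.items()):
                fh.write(f"{gid}\t{reason}\n")
        stats_path = out_dir / "repeat_stats.tsv"
        with open(stats_path, "w") as fh:
            cols = ("gene", "strain", "unit_len", "n_units", "copies", "gc", "pi")
            fh.write("\t".join(cols) + "\n")
            for row in stats_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    except OSError as exc:
        for p in list(out_dir.glob("*")):
            p.unlink(missing_ok=True)
        raise ScanError("report", str(exc)) from exc
    paths["skipped"] = skipped_path
    paths["stats"] = stats_path
    flagged = [c.gene_id for c in calls if c.flagged]
    log.info("%d calls, %d flagged", len(calls), len(flagged))
    return {"n_pairs": len(pairs), "n_skipped": len(skipped),
            "n_blocks": len(all_blocks), "flagged_genes": flagged,
            "paths": {k: str(v) for k, v in paths.items()}}
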