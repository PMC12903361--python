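"""Seeded synthetic-data generation with machine-readable ground truth.

Everything the pipeline consumes can be generated here: ortholog CDS
pairs with planted tandem arrays (unit length, per-allele copy number,
per-unit divergence, GC bias, non-repetitive flanks), annotated toy
genome pairs (FASTA + GFF3 with single- and multi-exon CDS on both
strands), and mosaic haplotypes assembled from donor segments.  All
randomness flows through numpy's PCG64 generator so the same seed yields
byte-identical fixtures on any platform.

Flanks are rejection-sampled to contain no exact repeat at the anchor
seed scale, either internally or against the planted array, so negative
controls are truly negative.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "VntrTruth",
    "MosaicTruth",
    "GenomeTruth",
    "GenomePair",
    "gen_vntr_pair",
    "gen_annotated_genome",
    "gen_mosaic_haplotype",
    "gen_donor_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SEED_SCALE = 12  # exact-repeat length the flank rejection guards against


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=n, p=p)
    return _BASES[draw].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-site substitutions (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _kmers(seq: str, k: int = SEED_SCALE) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _nonrepetitive_flank(rng: np.random.Generator, n: int,
                         avoid: set[str], gc: float = 0.5,
                         max_tries: int = 200) -> str:
    """A flank with unique internal k-mers, disjoint from ``avoid``."""
    for _ in range(max_tries):
        cand = _random_seq(rng, n, gc)
        km = [cand[i:i + SEED_SCALE] for i in range(len(cand) - SEED_SCALE + 1)]
        if len(set(km)) == len(km) and not (set(km) & avoid):
            return cand
    raise RuntimeError("could not sample a non-repetitive flank")


@dataclass(frozen=True)
class VntrTruth:
    """Ground truth for one planted VNTR ortholog pair."""

    gene_id: str
    unit_seq: str
    unit_len: int
    copies_a: int
    copies_b: int
    divergence: float
    flank_len: int
    gc: float
    seed: int
    a_span: tuple[int, int]  # array coordinates within allele A
    b_span: tuple[int, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def gen_vntr_pair(unit_len: int, copies_a: int, copies_b: int,
                  divergence: float = 0.0, flank_len: int = 1000,
                  gc: float = 0.5, seed: int = 0,
                  gene_id: str = "gene") -> tuple[str, str, VntrTruth]:
    """Two alleles of one gene differing in tandem-array copy number.

    A random ancestral unit of the requested GC is repeated ``copies_a``
    and ``copies_b`` times with i.i.d. per-site substitutions at
    ``divergence`` per copy; both arrays are embedded in flanks shared
    between the alleles and guaranteed non-repetitive at the seed scale.
    """
    if unit_len < 1 or copies_a < 1 or copies_b < 1:
        raise ValueError("unit_len and copy numbers must be >= 1")
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must lie in [0, 0.5)")
    if not (0.0 <= gc <= 1.0):
        raise ValueError(f"GC fraction {gc} is impossible")
    if unit_len < SEED_SCALE and gc in (0.0, 1.0):
        # a homopolymer-ish unit shorter than the seed cannot both satisfy
        # the GC request and stay detectable; refuse loudly
        raise ValueError("impossible GC for this unit length")
    rng = _rng(seed)
    unit = _random_seq(rng, unit_len, gc)

    def build_array(copies: int) -> str:
        return "".join(_mutate(rng, unit, divergence) for _ in range(copies))

    arr_a = build_array(copies_a)
    arr_b = build_array(copies_b)
    avoid = _kmers(arr_a) | _kmers(arr_b)
    left = _nonrepetitive_flank(rng, flank_len, avoid)
    avoid |= _kmers(left)
    right = _nonrepetitive_flank(rng, flank_len, avoid)
    seq_a = left + arr_a + right
    seq_b = left + arr_b + right
    truth = VntrTruth(
        gene_id=gene_id, unit_seq=unit, unit_len=unit_len,
        copies_a=copies_a, copies_b=copies_b, divergence=divergence,
        flank_len=flank_len, gc=gc, seed=seed,
        a_span=(flank_len, flank_len + len(arr_a)),
        b_span=(flank_len, flank_len + len(arr_b)))
    return seq_a, seq_b, truth


# ---------------------------------------------------------------------------
# annotated genome pairs


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    strand: str
    n_exons: int
    cds_ref: str
    cds_strain: str
    vntr: VntrTruth | None


@dataclass(frozen=True)
class GenomeTruth:
    seed: int
    genes: tuple[GeneTruth, ...]

    @property
    def polymorphic_genes(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes if g.vntr is not None)


@dataclass(frozen=True)
class GenomePair:
    ref_fasta: dict[str, str]
    ref_gff: str
    strain_fasta: dict[str, str]
    strain_gff: str
    truth: GenomeTruth

    def write(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        from .seqio import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_fasta": out / "ref.fa", "ref_gff": out / "ref.gff3",
            "strain_fasta": out / "strain.fa", "strain_gff": out / "strain.gff3",
            "truth": out / "truth.json",
        }
        write_fasta(self.ref_fasta, paths["ref_fasta"])
        write_fasta(self.strain_fasta, paths["strain_fasta"])
        paths["ref_gff"].write_text(self.ref_gff)
        paths["strain_gff"].write_text(self.strain_gff)
        paths["truth"].write_text(json.dumps({
            "seed": self.truth.seed,
            "polymorphic_genes": list(self.truth.polymorphic_genes),
            "genes": [{
                "gene_id": g.gene_id, "strand": g.strand,
                "n_exons": g.n_exons,
                "vntr": asdict(g.vntr) if g.vntr else None,
            } for g in self.truth.genes],
        }, indent=1))
        return {k: str(v) for k, v in paths.items()}


def _emit_gene(lines: list[str], chrom_parts: list[str], cursor: int,
               gene_id: str, cds: str, strand: str, n_exons: int,
               rng: np.random.Generator) -> int:
    """Append one gene (intergenic spacer + exons/introns) to a chromosome."""
    spacer = _random_seq(rng, int(rng.integers(300, 800)))
    chrom_parts.append(spacer)
    cursor += len(spacer)
    # split CDS into exons
    n_exons = min(n_exons, max(1, len(cds) // 60))
    cut_pool = rng.choice(np.arange(30, len(cds) - 30), size=max(0, n_exons - 1),
                          replace=False) if n_exons > 1 else np.array([], int)
    cuts = [0] + sorted(int(c) for c in cut_pool) + [len(cds)]
    pieces = [cds[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
    genomic_pieces = pieces if strand == "+" else \
        [_revcomp(p) for p in reversed(pieces)]
    exon_locs = []
    for i, piece in enumerate(genomic_pieces):
        if i > 0:
            intron = _random_seq(rng, int(rng.integers(80, 200)))
            chrom_parts.append(intron)
            cursor += len(intron)
        exon_locs.append((cursor, cursor + len(piece)))
        chrom_parts.append(piece)
        cursor += len(piece)
    gene_start = exon_locs[0][0]
    gene_end = exon_locs[-1][1]
    tid = f"{gene_id}.t1"
    lines.append(f"chr1\tsim\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t."
                 f"\tID={gene_id}")
    lines.append(f"chr1\tsim\tmRNA\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t."
                 f"\tID={tid};Parent={gene_id}")
    # CDS phases follow translation order
    order = exon_locs if strand == "+" else list(reversed(exon_locs))
    acc = 0
    phased = []
    for s, e in order:
        phased.append((s, e, (3 - acc % 3) % 3))
        acc += e - s
    for s, e, ph in sorted(phased):
        lines.append(f"chr1\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{ph}"
                     f"\tID=cds_{tid};Parent={tid}")
    return cursor


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gen_annotated_genome(n_genes: int, vntr_fraction: float, seed: int = 0,
                         snp_rate: float = 0.001) -> GenomePair:
    """A toy reference/strain genome pair with planted VNTR polymorphisms.

    Exactly ``round(n_genes * vntr_fraction)`` genes carry a planted
    copy-number difference large enough to leave the r band; the rest are
    ordinary CDS differing only by background SNPs at ``snp_rate``.
    Genes mix single- and multi-exon structures on both strands.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= vntr_fraction <= 1):
        raise ValueError("vntr_fraction must lie in [0, 1]")
    rng = _rng(seed)
    n_vntr = int(round(n_genes * vntr_fraction))
    vntr_idx = set(rng.choice(n_genes, size=n_vntr, replace=False).tolist())

    genes: list[GeneTruth] = []
    ref_lines = ["##gff-version 3"]
    strain_lines = ["##gff-version 3"]
    ref_parts: list[str] = []
    strain_parts: list[str] = []
    ref_cursor = strain_cursor = 0
    for i in range(n_genes):
        gid = f"g{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        if i in vntr_idx:
            unit_len = int(rng.integers(20, 61))
            copies_ref = int(rng.integers(7, 13))
            delta = int(rng.integers(3, 9))
            if rng.random() < 0.5:
                copies_strain = copies_ref + delta
            else:
                copies_strain = max(7, copies_ref - delta)
                if copies_strain == copies_ref:
                    copies_strain = copies_ref + delta
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cds_ref, cds_strain, vt = gen_vntr_pair(
                unit_len, copies_ref, copies_strain, divergence=0.0,
                flank_len=600, seed=sub_seed, gene_id=gid)
            vntr = vt
        else:
            cds_ref = _random_seq(rng, int(rng.integers(500, 2000)))
            cds_strain = _mutate(rng, cds_ref, snp_rate)
            vntr = None
        ref_cursor = _emit_gene(ref_lines, ref_parts, ref_cursor, gid,
                                cds_ref, strand, n_exons, rng)
        strain_cursor = _emit_gene(strain_lines, strain_parts, strain_cursor,
                                   gid, cds_strain, strand, n_exons, rng)
        genes.append(GeneTruth(gene_id=gid, strand=strand, n_exons=n_exons,
                               cds_ref=cds_ref, cds_strain=cds_strain,
                               vntr=vntr))
    tail_ref = _random_seq(rng, 300)
    tail_strain = _random_seq(rng, 300)
    return GenomePair(
        ref_fasta={"chr1": "".join(ref_parts) + tail_ref},
        ref_gff="\n".join(ref_lines) + "\n",
        strain_fasta={"chr1": "".join(strain_parts) + tail_strain},
        strain_gff="\n".join(strain_lines) + "\n",
        truth=GenomeTruth(seed=seed, genes=tuple(genes)))


# ---------------------------------------------------------------------------
# mosaic haplotypes


@dataclass(frozen=True)
class MosaicTruth:
    seed: int
    segments: tuple[tuple[str, int, int], ...]  # (label, start, end)
    window_len: int
    window_labels: tuple[str, ...]
    window_noise: tuple[int, ...]  # planted substitutions per window

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def gen_mosaic_haplotype(donors: dict[str, str],
                         plan: list[tuple[str, int]],
                         noise_snps_per_10kb: int = 0,
                         seed: int = 0,
                         window_len: int = 10_000
                         ) -> tuple[str, MosaicTruth]:
    """A query haplotype stitched from syntenic donor segments.

    Each plan entry (label, length) copies the corresponding coordinate
    range of that donor; lengths must be multiples of ``window_len`` and
    labels must exist in ``donors``.  ``noise_snps_per_10kb`` exact
    substitutions are planted per window at random positions, recorded in
    the truth.
    """
    for lab, length in plan:
        if lab not in donors:
            raise ValueError(f"plan references unknown donor {lab!r}")
        if length % window_len != 0:
            raise ValueError("plan segment lengths must be multiples of "
                             f"window_len={window_len}")
    total = sum(length for _, length in plan)
    for lab, _ in plan:
        if len(donors[lab]) < total:
            raise ValueError(f"donor {lab!r} is shorter than the plan total")
    rng = _rng(seed)
    parts: list[str] = []
    segments = []
    window_labels: list[str] = []
    window_noise: list[int] = []
    cursor = 0
    for lab, length in plan:
        piece = donors[lab][cursor:cursor + length]
        n_win = length // window_len
        mutated = []
        for w in range(n_win):
            win = np.frombuffer(
                piece[w * window_len:(w + 1) * window_len].encode("ascii"),
                dtype=np.uint8).copy()
            k = min(noise_snps_per_10kb, len(win))
            if k > 0:
                pos = rng.choice(len(win), size=k, replace=False)
                for p in pos:
                    choices = _BASES[_BASES != win[p]]
                    win[p] = rng.choice(choices)
            mutated.append(win.tobytes().decode("ascii"))
            window_labels.append(lab)
            window_noise.append(k)
        parts.append("".join(mutated))
        segments.append((lab, cursor, cursor + length))
        cursor += length
    truth = MosaicTruth(seed=seed, segments=tuple(segments),
                        window_len=window_len,
                        window_labels=tuple(window_labels),
                        window_noise=tuple(window_noise))
    return "".join(parts), truth


def gen_donor_panel(labels: list[str], length: int,
                    snps_per_10kb: int = 20, seed: int = 0) -> dict[str, str]:
    """Donor haplotypes diverged from a common ancestor.

    Each donor carries ``snps_per_10kb`` private substitutions per 10 kb,
    so pairwise donor divergence is about twice that density.
    """
    rng = _rng(seed)
    ancestor = _random_seq(rng, length)
    donors = {}
    for lab in labels:
        donors[lab] = _mutate(rng, ancestor, snps_per_10kb / 10_000)
    return donors
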