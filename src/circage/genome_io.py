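"""Genome, annotation and alignment data model.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GTF input (1-based inclusive) and BED output (0-based half-open)
convert at the boundary; nothing downstream of this module ever sees a
1-based coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


class GenomeIOError(ValueError):
    """Malformed genome/annotation input."""


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered chromosome names plus uppercase sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomeIOError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq:
                raise GenomeIOError(f"empty sequence for {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise GenomeIOError(f"non-DNA characters in {name!r}: {sorted(bad)}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased, order kept)."""
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise GenomeIOError(f"no records in FASTA {path}")
    return GenomeSequence(names, seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class Transcript:
    """Ordered exons of one transcript, with optional CDS sub-intervals.

    ``exons`` and ``cds`` are lists of 0-based half-open intervals sorted in
    genomic order; UTRs are derived (exon minus CDS, split by side of the
    CDS span, orientation given by the gene strand).
    """

    tx_id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise GenomeIOError(f"{self.tx_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise GenomeIOError(f"{self.tx_id}: overlapping exons")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise GenomeIOError(
                    f"{self.tx_id}: CDS ({cs},{ce}) not contained in any exon"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def utrs(self, strand: str) -> tuple[list[Interval], list[Interval]]:
        """(5'UTR, 3'UTR) genomic intervals; both empty for non-coding."""
        if not self.cds:
            return [], []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        left: list[Interval] = []
        right: list[Interval] = []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        return (left, right) if strand == "+" else (right, left)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise GenomeIOError(f"{self.gene_id}: no transcripts")

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts.values()))
        return (min(starts), max(ends))

    def longest_transcript(self) -> Transcript:
        """Reference transcript: most spliced sequence, ties by id."""
        return max(
            self.transcripts.values(), key=lambda t: (t.spliced_length(), t.tx_id)
        )

    def exon_union(self) -> list[Interval]:
        """Union of exon intervals over all transcripts (merged, sorted)."""
        ivs = sorted(iv for t in self.transcripts.values() for iv in t.exons)
        merged: list[Interval] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF (exon and CDS features) into :class:`GeneModel` objects.

    Coordinates convert from GTF 1-based inclusive to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # gene_id -> (chrom, strand, {tx_id: ([exons], [cds])})
    genes: dict[str, tuple[str, str, dict[str, tuple[list, list]]]] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid_attr = feat.attributes.get("gene_id")
        tid_attr = feat.attributes.get("transcript_id")
        if not gid_attr:
            raise GenomeIOError(
                f"{feat.featuretype} line at {feat.seqid}:{feat.start} lacks gene_id"
            )
        if not tid_attr:
            raise GenomeIOError(
                f"{feat.featuretype} line at {feat.seqid}:{feat.start} lacks transcript_id"
            )
        gid, tid = gid_attr[0], tid_attr[0]
        if gid not in genes:
            genes[gid] = (feat.seqid, feat.strand, {})
            order.append(gid)
        chrom, strand, txs = genes[gid]
        if feat.strand != strand:
            raise GenomeIOError(f"{gid}: inconsistent strand")
        exons, cds = txs.setdefault(tid, ([], []))
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        (exons if feat.featuretype == "exon" else cds).append(iv)
    models = []
    for gid in order:
        chrom, strand, txs = genes[gid]
        transcripts = {
            tid: Transcript(tid, exons, cds) for tid, (exons, cds) in txs.items()
        }
        models.append(GeneModel(gid, chrom, strand, transcripts))
    return models


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "circage") -> None:
    """Write exon/CDS GTF lines (1-based inclusive) for the given genes."""
    with open(path, "w") as fh:
        for g in genes:
            for tid in sorted(g.transcripts):
                tx = g.transcripts[tid]
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                for s, e in tx.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                for s, e in tx.cds:
                    fh.write(
                        f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# splice-site index


@dataclass(frozen=True)
class SpliceSiteIndex:
    """Annotated splice sites keyed by genomic coordinate.

    Donor positions are the transcription-direction 5' splice sites (exon
    genomic end on '+', exon genomic start on '-'); acceptors are the 3'
    sites (mirrored).  Entries are (chrom, position, strand).
    """

    donors: frozenset[tuple[str, int, str]]
    acceptors: frozenset[tuple[str, int, str]]

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel]) -> "SpliceSiteIndex":
        donors = set()
        acceptors = set()
        for g in genes:
            for tx in g.transcripts.values():
                for s, e in tx.exons:
                    if g.strand == "+":
                        donors.add((g.chrom, e, "+"))
                        acceptors.add((g.chrom, s, "+"))
                    else:
                        donors.add((g.chrom, s, "-"))
                        acceptors.add((g.chrom, e, "-"))
        return cls(frozenset(donors), frozenset(acceptors))

    def backsplice_strands(self, chrom: str, start: int, end: int) -> tuple[str, ...]:
        """Strands on which (start, end) is a valid back-splice junction.

        A back-splice joins a downstream donor to an upstream acceptor, so in
        genomic coordinates ``start`` must be an exon genomic start and
        ``end`` an exon genomic end on a common strand.
        """
        out = []
        if (chrom, start, "+") in self.acceptors and (chrom, end, "+") in self.donors:
            out.append("+")
        if (chrom, start, "-") in self.donors and (chrom, end, "-") in self.acceptors:
            out.append("-")
        return tuple(out)

    def exon_start_positions(self) -> dict[str, list[int]]:
        """Per-chromosome sorted genomic exon-start coordinates (any strand)."""
        pos: dict[str, set[int]] = {}
        for c, p, s in self.acceptors:
            if s == "+":
                pos.setdefault(c, set()).add(p)
        for c, p, s in self.donors:
            if s == "-":
                pos.setdefault(c, set()).add(p)
        return {c: sorted(v) for c, v in pos.items()}

    def exon_end_positions(self) -> dict[str, list[int]]:
        """Per-chromosome sorted genomic exon-end coordinates (any strand)."""
        pos: dict[str, set[int]] = {}
        for c, p, s in self.donors:
            if s == "+":
                pos.setdefault(c, set()).add(p)
        for c, p, s in self.acceptors:
            if s == "-":
                pos.setdefault(c, set()).add(p)
        return {c: sorted(v) for c, v in pos.items()}


def build_splice_index(genes: Iterable[GeneModel]) -> SpliceSiteIndex:
    return SpliceSiteIndex.from_genes(genes)


# ---------------------------------------------------------------------------
# alignments and library metadata


@dataclass
class FragmentAlignment:
    """Simplified paired-fragment alignment record.

    ``blocks`` holds, per mate, a sorted list of aligned genomic intervals.
    ``flag`` is one of 'contiguous', 'split' (forward-spliced) or
    'backsplice' (the mate blocks describe a head-to-tail junction read).
    """

    fragment_id: str
    library_id: str
    chrom: str
    blocks: tuple[tuple[Interval, ...], ...]
    strand: str
    flag: str = "contiguous"

    def __post_init__(self) -> None:
        for mate in self.blocks:
            if list(mate) != sorted(mate):
                raise GenomeIOError(f"{self.fragment_id}: unsorted blocks")

    def outer(self) -> Interval:
        starts = [iv[0] for mate in self.blocks for iv in mate]
        ends = [iv[1] for mate in self.blocks for iv in mate]
        return (min(starts), max(ends))


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    time_point: str
    replicate: int
    total_fragments: int

    def __post_init__(self) -> None:
        if self.total_fragments <= 0:
            raise GenomeIOError(f"{self.library_id}: total_fragments must be > 0")


def check_library_table(libraries: Sequence[LibraryMeta]) -> None:
    keys = [(m.time_point, m.replicate) for m in libraries]
    if len(set(keys)) != len(keys):
        raise GenomeIOError("duplicate (time_point, replicate) in library table")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Tunable thresholds of the discovery/quantification/statistics pipeline.

    Defaults follow the analysis conventions this package implements: a
    catalog cutoff of 12 deduplicated junction reads summed over all
    libraries, 6 reads per time-point for detection-based rules, 200-nt
    junction templates, 1.5-fold-change and P<0.05 calling thresholds with
    BH FDR < 0.2 for differential accumulation and FDR < 0.05 for the
    host-independence ratio test, and word size 7 for RCM search.
    """

    anchor_length: int = 20
    min_catalog_reads_total: int = 12
    min_timepoint_reads: int = 6
    template_length: int = 200
    fc_threshold: float = 1.5
    alpha: float = 0.05
    fdr_threshold_diff: float = 0.2
    fdr_threshold_ratio: float = 0.05
    rcm_word_size: int = 7
    read_length: int = 125
    min_junction_overlap: int = 8
    max_span: int = 25_000
    max_mismatches: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "anchor_length min_catalog_reads_total min_timepoint_reads "
            "template_length fc_threshold alpha fdr_threshold_diff "
            "fdr_threshold_ratio rcm_word_size read_length "
            "min_junction_overlap max_span"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.template_length % 2:
            raise ValueError("template_length must be even")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.anchor_length > self.read_length // 2:
            raise ValueError("anchor_length must be <= read_length/2")


# ---------------------------------------------------------------------------
# BED output


def write_bed(junctions: Sequence, path: str | Path) -> None:
    """Write a circRNA catalog as BED6 (0-based half-open), sorted."""
    rows = sorted(junctions, key=lambda j: (j.chrom, j.start, j.end))
    with open(path, "w") as fh:
        for j in rows:
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.circ_id}\t0\t{j.strand}\n")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))
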