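"""Back-splice junction discovery and the high-confidence filter cascade.

Discovery is anchor-based: terminal anchors of each read are placed
uniquely in the genome by exact match; a head-to-tail (reversed) anchor
pair is extended inward to a breakpoint that must coincide with annotated
exon edges (an annotated acceptor at the junction start, an annotated donor
at the junction end).  Candidates then pass the filter cascade: PCR
duplicate collapse, removal of junctions spanning multiple genes,
parental-gene assignment, and a minimum total read cutoff.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import (
    FragmentAlignment,
    GeneModel,
    GenomeSequence,
    Interval,
    PipelineConfig,
    SpliceSiteIndex,
    revcomp,
    write_fasta,
    GenomeSequence as _GS,
)
from .simulate import ReadPair, spliced_sequence

JunctionKey = tuple[str, int, int, str]


@dataclass
class SupportRecord:
    """One junction-supporting fragment: library plus the genomic block
    structure of its placed reads (the deduplication key)."""

    fragment_id: str
    library_id: str
    blocks: tuple


@dataclass
class BackspliceCandidate:
    chrom: str
    start: int
    end: int
    strands: tuple[str, ...]
    support: list[SupportRecord] = field(default_factory=list)
    splice_site_matched: bool = True

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CircJunction:
    """One catalog entry; identity is (chrom, start, end, strand)."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DetectionStats:
    reads_seen: int = 0
    anchor_ambiguous: int = 0
    no_annotated_breakpoint: int = 0
    candidates_emitted: int = 0
    multi_gene_removed: int = 0
    no_gene_removed: int = 0


class AnchorIndex:
    """Exact k-mer index of the genome for unique anchor placement."""

    AMBIG = ("*", -1)

    def __init__(self, genome: GenomeSequence, k: int):
        self.k = k
        self.pos: dict[str, tuple[str, int]] = {}
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in self.pos:
                    self.pos[kmer] = self.AMBIG
                else:
                    self.pos[kmer] = (chrom, i)

    def lookup(self, kmer: str) -> tuple[str, int] | None:
        """Unique genomic placement of ``kmer``, else None (absent/ambiguous)."""
        hit = self.pos.get(kmer)
        if hit is None or hit == self.AMBIG:
            return None
        return hit


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_breakpoint(
    seq: str,
    chrom: str,
    ph: int,
    pt: int,
    genome: GenomeSequence,
    splice_index: SpliceSiteIndex,
    exon_ends: dict[str, list[int]],
    cfg: PipelineConfig,
):
    """Find the annotated breakpoint for a head-to-tail anchor pair.

    The read is modelled as genome[end-k':end] + genome[start:start+(L-k')]
    for an unknown split k'; only splits whose donor coordinate (ph + k')
    is an annotated exon end and whose acceptor coordinate is an annotated
    exon start are considered.  The ``min_junction_overlap`` nt on each side
    of the split must match near-exactly (at most one mismatch per side), so
    a read from an unannotated junction a few nt away cannot be snapped onto
    the nearest annotated edge.  Ties break by most matched bases, then
    smallest genomic span.
    """
    L = len(seq)
    k = cfg.anchor_length
    w = cfg.min_junction_overlap
    ends = exon_ends.get(chrom, [])
    g = genome.sequences[chrom]
    lo = bisect_left(ends, ph + k)
    hi = bisect_right(ends, ph + L - k)
    best = None
    for e in ends[lo:hi]:
        kp = e - ph
        s = pt + k - (L - kp)
        if s < 0 or s >= e:
            continue
        strands = splice_index.backsplice_strands(chrom, s, e)
        if not strands:
            continue
        mism = _mismatches(seq[:kp], g[ph:e]) + _mismatches(seq[kp:], g[s : s + L - kp])
        if mism > cfg.max_mismatches:
            continue
        if _mismatches(seq[kp - w : kp], g[e - w : e]) > 1:
            continue
        if _mismatches(seq[kp : kp + w], g[s : s + w]) > 1:
            continue
        cand = (L - mism, -(e - s), s, e, strands, kp)
        if best is None or cand > best:
            best = cand
    return best


def find_backsplice_candidates(
    reads: dict[str, list[ReadPair]] | Sequence[FragmentAlignment],
    genome: GenomeSequence,
    splice_index: SpliceSiteIndex,
    cfg: PipelineConfig,
    stats: DetectionStats | None = None,
) -> list[BackspliceCandidate]:
    """Discover back-splice candidates from reads or pre-aligned fragments.

    ``reads`` is either a mapping ``library_id -> [ReadPair]`` (raw-read
    path) or a sequence of :class:`FragmentAlignment` records; both paths
    produce the same candidate structure and share the annotated-splice-site
    restriction.
    """
    stats = stats if stats is not None else DetectionStats()
    if isinstance(reads, dict):
        return _candidates_from_reads(reads, genome, splice_index, cfg, stats)
    return _candidates_from_alignments(reads, splice_index, cfg, stats)


def _candidates_from_reads(
    reads: dict[str, list[ReadPair]],
    genome: GenomeSequence,
    splice_index: SpliceSiteIndex,
    cfg: PipelineConfig,
    stats: DetectionStats,
) -> list[BackspliceCandidate]:
    index = AnchorIndex(genome, cfg.anchor_length)
    exon_ends = splice_index.exon_end_positions()
    candidates: dict[tuple[str, int, int], BackspliceCandidate] = {}
    for lib, pairs in reads.items():
        for pair in pairs:
            frag_hits: list[tuple[int, tuple]] = []
            for mate, read in enumerate((pair.r1, pair.r2)):
                stats.reads_seen += 1
                hit = _place_backsplice_read(
                    read, genome, index, splice_index, exon_ends, cfg, stats
                )
                if hit is not None:
                    frag_hits.append((mate, hit))
            if not frag_hits:
                continue
            junctions = {(h[1][0], h[1][2], h[1][3]) for h in frag_hits}
            if len(junctions) > 1:
                continue  # mates disagree; discard fragment
            chrom, s, e = junctions.pop()
            strands = frag_hits[0][1][4]
            blocks = tuple(
                (mate, h[5]) for mate, h in frag_hits
            )  # (mate, block structure)
            cand = candidates.get((chrom, s, e))
            if cand is None:
                cand = BackspliceCandidate(chrom, s, e, strands)
                candidates[(chrom, s, e)] = cand
                stats.candidates_emitted += 1
            cand.support.append(SupportRecord(pair.fragment_id, lib, blocks))
    return list(candidates.values())


def _place_backsplice_read(
    read: str,
    genome: GenomeSequence,
    index: AnchorIndex,
    splice_index: SpliceSiteIndex,
    exon_ends: dict[str, list[int]],
    cfg: PipelineConfig,
    stats: DetectionStats,
):
    """Try both orientations of a read; return the best annotated-breakpoint
    placement as (chrom, matched, start, end, strands, blocks) or None."""
    k = cfg.anchor_length
    L = len(read)
    if L < 2 * k:
        return None
    best = None
    for seq in (read, revcomp(read)):
        head = index.lookup(seq[:k])
        tail = index.lookup(seq[-k:])
        if head is None or tail is None:
            continue
        (ch, ph), (ct, pt) = head, tail
        if ch != ct:
            continue
        if pt >= ph:  # collinear (contiguous or forward-spliced): not a backsplice
            continue
        if ph + L - pt > cfg.max_span:
            continue
        ext = _extend_breakpoint(seq, ch, ph, pt, genome, splice_index, exon_ends, cfg)
        if ext is None:
            stats.no_annotated_breakpoint += 1
            continue
        matched, negspan, s, e, strands, kp = ext
        blocks = ((s, s + L - kp), (e - kp, e))
        cand = (ch, matched, s, e, strands, blocks)
        if best is None or matched > best[1]:
            best = cand
    return best


def _candidates_from_alignments(
    alignments: Sequence[FragmentAlignment],
    splice_index: SpliceSiteIndex,
    cfg: PipelineConfig,
    stats: DetectionStats,
) -> list[BackspliceCandidate]:
    candidates: dict[tuple[str, int, int], BackspliceCandidate] = {}
    for aln in alignments:
        if aln.flag != "backsplice":
            continue
        stats.reads_seen += len(aln.blocks)
        s, e = aln.outer()
        strands = splice_index.backsplice_strands(aln.chrom, s, e)
        if not strands:
            stats.no_annotated_breakpoint += 1
            continue
        # require anchor-length support on both sides of the junction
        first = min(iv for mate in aln.blocks for iv in mate)
        last = max(iv for mate in aln.blocks for iv in mate)
        if first[1] - first[0] < cfg.anchor_length or last[1] - last[0] < cfg.anchor_length:
            continue
        cand = candidates.get((aln.chrom, s, e))
        if cand is None:
            cand = BackspliceCandidate(aln.chrom, s, e, strands)
            candidates[(aln.chrom, s, e)] = cand
            stats.candidates_emitted += 1
        cand.support.append(
            SupportRecord(aln.fragment_id, aln.library_id, aln.blocks)
        )
    return list(candidates.values())


# ---------------------------------------------------------------------------
# filter cascade


def dedup_and_merge(
    candidates: Iterable[BackspliceCandidate],
    genes: Sequence[GeneModel],
    cfg: PipelineConfig,
    stats: DetectionStats | None = None,
) -> list[CircJunction]:
    """Collapse PCR duplicates, drop multi-gene and gene-less junctions,
    and assign each surviving junction to its single parental gene.

    PCR duplicates are supporting fragments from the same library whose
    placed reads have identical coordinates.  A junction is removed when its
    span overlaps exons of more than one gene, or of none.
    """
    stats = stats if stats is not None else DetectionStats()
    junctions: list[CircJunction] = []
    for cand in candidates:
        hosts = [
            g
            for g in genes
            if g.chrom == cand.chrom
            and any(s < cand.end and e > cand.start for s, e in g.exon_union())
        ]
        if len(hosts) == 0:
            stats.no_gene_removed += 1
            continue
        if len(hosts) > 1:
            stats.multi_gene_removed += 1
            continue
        host = hosts[0]
        counts: dict[str, int] = {}
        seen: set = set()
        for rec in cand.support:
            key = (rec.library_id, rec.blocks)
            if key in seen:
                continue
            seen.add(key)
            counts[rec.library_id] = counts.get(rec.library_id, 0) + 1
        junctions.append(
            CircJunction(
                "", cand.chrom, cand.start, cand.end, host.strand, host.gene_id, counts
            )
        )
    return junctions


def apply_catalog_cutoff(
    junctions: Iterable[CircJunction], cfg: PipelineConfig
) -> list[CircJunction]:
    """Keep junctions with >= ``min_catalog_reads_total`` deduplicated reads
    summed over all libraries; assign serial ids in coordinate order."""
    kept = [j for j in junctions if j.total >= cfg.min_catalog_reads_total]
    kept.sort(key=lambda j: (j.chrom, j.start, j.end))
    for i, j in enumerate(kept, start=1):
        j.circ_id = f"circ_{i:07d}"
    return kept


# ---------------------------------------------------------------------------
# junction templates


def circle_exons(junction: CircJunction, genes: Sequence[GeneModel]) -> list[Interval]:
    """Exons of the host gene's reference transcript inside the junction span."""
    host = next(g for g in genes if g.gene_id == junction.host_gene)
    exons = [
        (s, e)
        for s, e in host.longest_transcript().exons
        if s >= junction.start and e <= junction.end
    ]
    if not exons:
        raise ValueError(f"{junction.circ_id}: no annotated exon inside span")
    return exons


def circle_sequence(
    junction: CircJunction, genes: Sequence[GeneModel], genome: GenomeSequence
) -> str:
    """Annotation-spliced circle sequence in transcript orientation."""
    return spliced_sequence(
        genome, junction.chrom, circle_exons(junction, genes), junction.strand
    )


def build_junction_templates(
    catalog: Sequence[CircJunction],
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    cfg: PipelineConfig,
) -> dict[str, str]:
    """Junction-spanning templates: the circle's last ``template_length/2``
    nt joined to its first ``template_length/2`` nt, back-splice point at
    the midpoint.  Circles shorter than the template wrap."""
    half = cfg.template_length // 2
    templates = {}
    for j in catalog:
        circ = circle_sequence(j, genes, genome)
        reps = -(-half // len(circ)) + 1  # enough copies to cover both halves
        tiled = circ * reps
        templates[j.circ_id] = tiled[-half:] + tiled[:half]
    return templates


def write_templates(templates: dict[str, str], path) -> None:
    gs = _GS(list(templates), dict(templates))
    write_fasta(gs, path)
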