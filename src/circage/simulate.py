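"""Synthetic total-RNA-seq generator with planted circRNAs.

Emulates the study design the pipeline targets: 12 libraries (4 aging
time-points x 3 replicates) of paired-end 125-nt reads drawn from a toy
genome, mixing linear mRNA fragments (flat across age by default) with
circRNA fragments whose Poisson means rise with age, plus reverse
complementary matches (RCMs) planted into the introns flanking a
configurable fraction of circRNA loci.  Every random draw is logged into a
truth table so each downstream stage can be tested against a known answer.

Fragments, not transcripts, are the simulation unit.  Circular fragments
are drawn from the doubled circle sequence, which gives uniform coverage
across the back-splice point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .genome_io import (
    GeneModel,
    GenomeSequence,
    Interval,
    LibraryMeta,
    Transcript,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions.

    ``age_multipliers`` scale the per-library circRNA fragment mean per
    time-point while ``linear_mean`` (fragments per gene per library) stays
    constant, reproducing age-accumulation that is independent of host-gene
    expression.  Lengths are in nucleotides; fragment counts are Poisson
    means.
    """

    time_points: tuple[str, ...] = ("L4", "D1", "D7", "D10")
    n_replicates: int = 3
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (150, 350)
    intron_length: tuple[int, int] = (120, 400)
    intergenic_length: tuple[int, int] = (200, 500)
    n_circ_genes: int = 10
    circ_first_exon_rank: int = 2
    circ_n_exons: tuple[int, int] = (1, 3)
    base_circ_mean: float = 50.0
    age_multipliers: tuple[float, ...] = (1.0, 1.2, 5.0, 6.0)
    linear_mean: float = 100.0
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    read_length: int = 125
    error_rate: float = 0.0
    rcm_fraction: float = 0.8
    rcm_length: int = 30
    junction_overlap_min: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.age_multipliers) != len(self.time_points):
            raise SimulationError("one age multiplier per time-point required")
        if any(m < 0 for m in self.age_multipliers):
            raise SimulationError("age multipliers must be >= 0")
        if not 0 <= self.error_rate < 0.1:
            raise SimulationError("error_rate must be in [0, 0.1)")
        if self.read_length > self.fragment_length_mean:
            raise SimulationError("read_length must be <= mean fragment length")
        if self.n_circ_genes > self.n_genes:
            raise SimulationError("n_circ_genes > n_genes")
        if self.circ_first_exon_rank < 2:
            raise SimulationError(
                "circ_first_exon_rank must be >= 2 (flanking intron required)"
            )

    @property
    def library_ids(self) -> list[str]:
        return [
            f"{tp}_r{r}"
            for tp in self.time_points
            for r in range(1, self.n_replicates + 1)
        ]

    def multiplier_for(self, library_id: str) -> float:
        tp = library_id.rsplit("_r", 1)[0]
        return self.age_multipliers[self.time_points.index(tp)]


class ReadPair(NamedTuple):
    fragment_id: str
    r1: str
    r2: str


@dataclass
class CircLocus:
    """A planted circRNA locus on the (single) transcript of a gene.

    ``first_idx``/``last_idx`` are genomic-order exon indices on the
    reference transcript; ``start``/``end`` the genomic junction interval.
    """

    gene_id: str
    chrom: str
    strand: str
    first_idx: int
    last_idx: int
    start: int
    end: int

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class PlantedCirc:
    locus: CircLocus
    circle_length: int
    expected: dict[str, float] = field(default_factory=dict)
    emitted: dict[str, int] = field(default_factory=dict)
    junction_spanning: dict[str, int] = field(default_factory=dict)
    junction_unique: dict[str, int] = field(default_factory=dict)


@dataclass
class PlantedRCM:
    gene_id: str
    upstream_interval: Interval
    downstream_interval: Interval
    seq: str


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset (the oracle for all tests)."""

    circs: list[PlantedCirc]
    linear_counts: dict[str, dict[str, int]]
    rcms: dict[str, PlantedRCM]
    config: SimConfig

    def junction_keys(self) -> set[tuple[str, int, int, str]]:
        return {c.locus.key for c in self.circs}


@dataclass
class SimDataset:
    genome: GenomeSequence
    genes: list[GeneModel]
    circ_loci: list[CircLocus]
    reads: dict[str, list[ReadPair]]
    alignments: list
    truth: SimTruth
    libraries: list[LibraryMeta]


# ---------------------------------------------------------------------------
# genome / annotation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def generate_genome_and_annotation(
    cfg: SimConfig,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Lay out ``n_genes`` non-overlapping single-transcript genes on one
    chromosome of i.i.d. uniform sequence.  Deterministic given the seed.

    Each gene's CDS runs from the midpoint of its first exon to the midpoint
    of its last exon, so internal exons are pure CDS and the terminal exons
    carry the UTRs.  Strands alternate so both orientations are exercised.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    chrom = "chrS1"
    for gi in range(cfg.n_genes):
        gap = int(rng.integers(cfg.intergenic_length[0], cfg.intergenic_length[1] + 1))
        pieces.append(_random_seq(rng, gap))
        pos += gap
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons: list[Interval] = []
        for ei in range(n_ex):
            if ei > 0:
                ilen = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
                pieces.append(_random_seq(rng, ilen))
                pos += ilen
            elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            pieces.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        strand = "+" if gi % 2 == 0 else "-"
        cds_lo = (exons[0][0] + exons[0][1]) // 2
        cds_hi = (exons[-1][0] + exons[-1][1]) // 2
        cds = [
            (max(s, cds_lo), min(e, cds_hi))
            for s, e in exons
            if min(e, cds_hi) > max(s, cds_lo)
        ]
        gid = f"g{gi + 1:04d}"
        tx = Transcript(f"{gid}.t1", exons, cds)
        genes.append(GeneModel(gid, chrom, strand, {f"{gid}.t1": tx}))
    pieces.append(_random_seq(rng, int(rng.integers(*cfg.intergenic_length))))
    genome = GenomeSequence([chrom], {chrom: "".join(pieces)})
    return genome, genes


def plan_circ_loci(genes: list[GeneModel], cfg: SimConfig) -> list[CircLocus]:
    """Pick circRNA-hosting genes and exon spans, deterministically.

    The first circularized exon has transcript rank ``circ_first_exon_rank``
    and the span never reaches the terminal exon, so a flanking intron
    exists on both sides.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    eligible = [
        g
        for g in genes
        if len(g.longest_transcript().exons)
        >= cfg.circ_first_exon_rank + cfg.circ_n_exons[0]
    ]
    if len(eligible) < cfg.n_circ_genes:
        raise SimulationError(
            f"only {len(eligible)} genes can host a circRNA; "
            f"{cfg.n_circ_genes} requested"
        )
    chosen = [eligible[i] for i in rng.choice(len(eligible), cfg.n_circ_genes, replace=False)]
    chosen.sort(key=lambda g: g.span[0])
    loci = []
    for g in chosen:
        exons = g.longest_transcript().exons
        n = len(exons)
        max_k = min(cfg.circ_n_exons[1], n - cfg.circ_first_exon_rank)
        k = int(rng.integers(cfg.circ_n_exons[0], max_k + 1))
        first_rank = cfg.circ_first_exon_rank
        last_rank = first_rank + k - 1
        if g.strand == "+":
            fi, li = first_rank - 1, last_rank - 1
        else:
            fi, li = n - last_rank, n - first_rank
        loci.append(
            CircLocus(
                g.gene_id, g.chrom, g.strand, fi, li, exons[fi][0], exons[li][1]
            )
        )
    return loci


def plant_rcms(
    genome: GenomeSequence,
    genes: list[GeneModel],
    circ_loci: list[CircLocus],
    cfg: SimConfig,
) -> tuple[GenomeSequence, dict[str, PlantedRCM]]:
    """Write a random ``rcm_length``-mer into the upstream flanking intron
    and its reverse complement into the downstream flanking intron of a
    ``rcm_fraction`` of circRNA loci.  Returns the edited genome and the
    planted positions.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    n_plant = int(round(cfg.rcm_fraction * len(circ_loci)))
    order = rng.permutation(len(circ_loci))[:n_plant]
    gene_by_id = {g.gene_id: g for g in genes}
    seq = bytearray(genome.sequences[genome.chrom_names[0]], "ascii")
    planted: dict[str, PlantedRCM] = {}
    for idx in sorted(order):
        locus = circ_loci[idx]
        exons = gene_by_id[locus.gene_id].longest_transcript().exons
        up_iv = (exons[locus.first_idx - 1][1], exons[locus.first_idx][0])
        down_iv = (exons[locus.last_idx][1], exons[locus.last_idx + 1][0])
        if min(up_iv[1] - up_iv[0], down_iv[1] - down_iv[0]) < cfg.rcm_length + 10:
            warnings.warn(
                f"{locus.gene_id}: flanking intron too short for RCM, skipped"
            )
            continue
        insert = _random_seq(rng, cfg.rcm_length)
        up_pos = int(rng.integers(up_iv[0] + 5, up_iv[1] - cfg.rcm_length - 5 + 1))
        down_pos = int(rng.integers(down_iv[0] + 5, down_iv[1] - cfg.rcm_length - 5 + 1))
        seq[up_pos : up_pos + cfg.rcm_length] = insert.encode()
        seq[down_pos : down_pos + cfg.rcm_length] = revcomp(insert).encode()
        planted[locus.gene_id] = PlantedRCM(
            locus.gene_id,
            (up_pos, up_pos + cfg.rcm_length),
            (down_pos, down_pos + cfg.rcm_length),
            insert,
        )
    chrom = genome.chrom_names[0]
    return GenomeSequence([chrom], {chrom: seq.decode()}), planted


# ---------------------------------------------------------------------------
# spliced-coordinate helpers


def spliced_sequence(genome: GenomeSequence, chrom: str, exons: list[Interval], strand: str) -> str:
    s = "".join(genome.fetch(chrom, a, b) for a, b in exons)
    return s if strand == "+" else revcomp(s)


def transcript_interval_to_blocks(
    exons: list[Interval], strand: str, start: int, end: int
) -> list[Interval]:
    """Map a transcript-orientation spliced interval to genomic blocks.

    ``exons`` are genomic-order intervals of the spliced unit; the returned
    blocks are genomic-order 0-based half-open intervals.
    """
    total = sum(e - s for s, e in exons)
    if not 0 <= start < end <= total:
        raise ValueError("interval outside spliced unit")
    if strand == "-":
        start, end = total - end, total - start
    blocks = []
    off = 0
    for s, e in exons:
        lo = max(start, off)
        hi = min(end, off + (e - s))
        if lo < hi:
            blocks.append((s + lo - off, s + hi - off))
        off += e - s
    return blocks


# ---------------------------------------------------------------------------
# read emission


def apply_errors(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Apply i.i.d. substitution errors to equal-length reads (vectorized)."""
    if rate <= 0 or not reads:
        return reads
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).copy()
    arr = arr.reshape(len(reads), len(reads[0]))
    hit = rng.random(arr.shape) < rate
    n_hit = int(hit.sum())
    if n_hit:
        idx = _BASE_INDEX[arr[hit]]
        arr[hit] = _BASES[(idx + rng.integers(1, 4, n_hit)) % 4]
    flat = arr.tobytes().decode()
    w = arr.shape[1]
    return [flat[i * w : (i + 1) * w] for i in range(len(reads))]


def _fragment_lengths(
    rng: np.random.Generator, n: int, cfg: SimConfig, upper: int
) -> np.ndarray:
    ln = np.rint(
        rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, n)
    ).astype(int)
    return np.clip(ln, cfg.read_length, upper)


def simulate_libraries(
    genome: GenomeSequence,
    genes: list[GeneModel],
    circ_loci: list[CircLocus],
    cfg: SimConfig,
    rcms: dict[str, PlantedRCM] | None = None,
    emit_alignments: bool = True,
) -> tuple[dict[str, list[ReadPair]], list, SimTruth, list[LibraryMeta]]:
    """Draw fragments and emit reads for every library.

    Linear fragments per gene are Poisson(``linear_mean``) with positions
    uniform along the spliced mRNA; circRNA fragments per locus are
    Poisson(``base_circ_mean`` x age multiplier) with start offsets uniform
    around the circle (drawn from the doubled circle sequence).  Truth
    records, per locus and library: the expected mean, the number of
    fragments emitted, the number whose reads span the back-splice point
    with at least ``junction_overlap_min`` nt on each side, and the latter
    after collapsing fragments with identical junction-read placements
    (PCR-duplicate semantics used by quantification).
    """
    from .genome_io import FragmentAlignment  # local to avoid cycle at import time

    rng = np.random.default_rng(cfg.rng_seed + 3)
    gene_by_id = {g.gene_id: g for g in genes}
    L = cfg.read_length
    min_ov = cfg.junction_overlap_min
    half_t = 100  # template half-length used only to express dedup keys

    mrna: dict[str, tuple[str, list[Interval], str]] = {}
    for g in genes:
        tx = g.longest_transcript()
        mrna[g.gene_id] = (
            spliced_sequence(genome, g.chrom, tx.exons, g.strand),
            tx.exons,
            g.strand,
        )

    circ_truth = []
    circle_info = {}
    for locus in circ_loci:
        g = gene_by_id[locus.gene_id]
        exons = g.longest_transcript().exons[locus.first_idx : locus.last_idx + 1]
        circ_seq = spliced_sequence(genome, g.chrom, exons, g.strand)
        pc = PlantedCirc(locus, len(circ_seq))
        circ_truth.append(pc)
        circle_info[locus.gene_id] = (circ_seq + circ_seq, len(circ_seq), exons, pc)

    reads: dict[str, list[ReadPair]] = {}
    alignments: list = []
    linear_counts: dict[str, dict[str, int]] = {g.gene_id: {} for g in genes}
    libraries: list[LibraryMeta] = []

    for tp, mult in zip(cfg.time_points, cfg.age_multipliers):
        for rep in range(1, cfg.n_replicates + 1):
            lib = f"{tp}_r{rep}"
            lib_reads: list[str] = []
            lib_pairs_meta: list[str] = []
            serial = 0

            # linear mRNA fragments
            for g in genes:
                seq, exons, strand = mrna[g.gene_id]
                mlen = len(seq)
                n = int(rng.poisson(cfg.linear_mean))
                linear_counts[g.gene_id][lib] = n
                lens = _fragment_lengths(rng, n, cfg, mlen)
                starts = (rng.random(n) * (mlen - lens + 1)).astype(int)
                for s, fl in zip(starts, lens):
                    frag = seq[s : s + fl]
                    fid = f"{lib}:{serial}"
                    serial += 1
                    lib_reads.append(frag[:L])
                    lib_reads.append(revcomp(frag[-L:]))
                    lib_pairs_meta.append(fid)
                    if emit_alignments:
                        b1 = transcript_interval_to_blocks(exons, strand, int(s), int(s) + L)
                        b2 = transcript_interval_to_blocks(
                            exons, strand, int(s) + int(fl) - L, int(s) + int(fl)
                        )
                        flag = "split" if max(len(b1), len(b2)) > 1 else "contiguous"
                        alignments.append(
                            FragmentAlignment(
                                fid, lib, g.chrom, (tuple(b1), tuple(b2)), strand, flag
                            )
                        )

            # circRNA junction-region fragments
            for locus in circ_loci:
                doubled, lc, exons, pc = circle_info[locus.gene_id]
                mean = cfg.base_circ_mean * mult
                pc.expected[lib] = mean
                n = int(rng.poisson(mean)) if mean > 0 else 0
                pc.emitted[lib] = n
                lens = _fragment_lengths(rng, n, cfg, lc)
                offs = rng.integers(0, lc, n) if n else np.array([], dtype=int)
                keys = set()
                n_span = 0
                for o, fl in zip(offs, lens):
                    o, fl = int(o), int(fl)
                    frag = doubled[o : o + fl]
                    fid = f"{lib}:{serial}"
                    serial += 1
                    lib_reads.append(frag[:L])
                    lib_reads.append(revcomp(frag[-L:]))
                    lib_pairs_meta.append(fid)
                    # junction-crossing geometry (circle coordinate lc = junction)
                    key = []
                    for mate, (a, b) in enumerate(((o, o + L), (o + fl - L, o + fl))):
                        if a < lc < b:
                            left, right = lc - a, b - lc
                            if left >= min_ov and right >= min_ov:
                                key.append((mate, half_t - left))
                    if key:
                        n_span += 1
                        keys.add(tuple(key))
                    if emit_alignments:
                        mate_blocks = []
                        crossing = False
                        for a, b in ((o, o + L), (o + fl - L, o + fl)):
                            if b <= lc:
                                blk = transcript_interval_to_blocks(exons, locus.strand, a, b)
                            elif a >= lc:
                                blk = transcript_interval_to_blocks(
                                    exons, locus.strand, a - lc, b - lc
                                )
                            else:
                                crossing = True
                                blk = sorted(
                                    transcript_interval_to_blocks(exons, locus.strand, a, lc)
                                    + transcript_interval_to_blocks(
                                        exons, locus.strand, 0, b - lc
                                    )
                                )
                            mate_blocks.append(tuple(blk))
                        alignments.append(
                            FragmentAlignment(
                                fid,
                                lib,
                                locus.chrom,
                                tuple(mate_blocks),
                                locus.strand,
                                "backsplice" if crossing else "split",
                            )
                        )
                pc.junction_spanning[lib] = n_span
                pc.junction_unique[lib] = len(keys)

            lib_reads = apply_errors(lib_reads, cfg.error_rate, rng)
            reads[lib] = [
                ReadPair(fid, lib_reads[2 * i], lib_reads[2 * i + 1])
                for i, fid in enumerate(lib_pairs_meta)
            ]
            libraries.append(LibraryMeta(lib, tp, rep, len(lib_pairs_meta)))

    truth = SimTruth(circ_truth, linear_counts, rcms or {}, cfg)
    return reads, alignments, truth, libraries


def simulate_dataset(cfg: SimConfig, emit_alignments: bool = True) -> SimDataset:
    """Full generator: genome, annotation, planted circRNAs/RCMs, reads, truth."""
    genome, genes = generate_genome_and_annotation(cfg)
    circ_loci = plan_circ_loci(genes, cfg)
    genome, rcms = plant_rcms(genome, genes, circ_loci, cfg)
    reads, alignments, truth, libraries = simulate_libraries(
        genome, genes, circ_loci, cfg, rcms, emit_alignments=emit_alignments
    )
    return SimDataset(genome, genes, circ_loci, reads, alignments, truth, libraries)


# ---------------------------------------------------------------------------
# count-level generator (for statistical calibration and power studies)


def simulate_counts(
    cfg: SimConfig,
    n_circ: int,
    library_size: int = 1_000_000,
    rng: np.random.Generator | None = None,
):
    """Draw per-library circular and host-linear counts without emitting reads.

    Circular counts are Poisson(``base_circ_mean`` x age multiplier), linear
    host counts Poisson(``linear_mean``), one host gene per circRNA.  The
    library size is a fixed sequencing depth, mirroring real libraries in
    which junction reads are a negligible share of the total.  Returns
    ``(circ_counts, linear_counts, libraries)`` as pandas DataFrames indexed
    by circRNA id with one column per library.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(cfg.rng_seed)
    libs = cfg.library_ids
    mult = np.repeat(cfg.age_multipliers, cfg.n_replicates)
    circ = rng.poisson(
        np.outer(np.full(n_circ, cfg.base_circ_mean), mult)
    )
    lin = rng.poisson(cfg.linear_mean, size=(n_circ, len(libs)))
    ids = [f"sim_circ_{i + 1:05d}" for i in range(n_circ)]
    circ_df = pd.DataFrame(circ, index=ids, columns=libs)
    lin_df = pd.DataFrame(lin, index=ids, columns=libs)
    libraries = [
        LibraryMeta(lib, lib.rsplit("_r", 1)[0], int(lib.rsplit("_r", 1)[1]), library_size)
        for lib in libs
    ]
    return circ_df, lin_df, libraries


# ---------------------------------------------------------------------------
# file output


def write_fastq(reads: dict[str, list[ReadPair]], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lib, pairs in reads.items():
        for mate in (1, 2):
            with open(outdir / f"lib_{lib}_R{mate}.fastq", "w") as fh:
                for p in pairs:
                    seq = p.r1 if mate == 1 else p.r2
                    fh.write(f"@{p.fragment_id}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_library_table(libraries: Iterable[LibraryMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\ttime_point\treplicate\ttotal_fragments\n")
        for m in libraries:
            fh.write(f"{m.library_id}\t{m.time_point}\t{m.replicate}\t{m.total_fragments}\n")
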