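"""Genomic-feature summaries of the catalog and reverse-complementary-match
(RCM) analysis of circRNA-flanking introns.

RCM search is an ungapped seed-and-extend: exact ``word_size`` matches
between the upstream intron and the reverse complement of the downstream
intron are extended in both directions with +1/-2 match/mismatch scoring
and an X-drop of 6, keeping hits with score >= 10.  Enrichment of RCMs at
circRNA loci over position-matched control exons (exons 2 and 8 of
non-circRNA genes) is tested by Kruskal-Wallis with Dunn's post-hoc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import CircJunction
from .genome_io import GeneModel, GenomeSequence, PipelineConfig, revcomp
from .rank_tests import dunn, kruskal_wallis

REGION_CLASSES = ("CDS", "5'UTR+CDS", "3'UTR+CDS", "5'UTR", "3'UTR", "other")


class FlankingIntronError(ValueError):
    """Locus at a transcript terminus: no flanking intron on one side."""


def _overlaps(iv: tuple[int, int], ivs: Sequence[tuple[int, int]]) -> bool:
    return any(s < iv[1] and e > iv[0] for s, e in ivs)


def _span_exon_indices(
    junction: CircJunction, gene: GeneModel
) -> tuple[list[tuple[int, int]], int, int]:
    exons = gene.longest_transcript().exons
    idx = [i for i, (s, e) in enumerate(exons) if s >= junction.start and e <= junction.end]
    if not idx:
        raise ValueError(f"{junction.circ_id}: no reference exon inside span")
    return exons, idx[0], idx[-1]


def classify_region(junction: CircJunction, genes: Sequence[GeneModel]) -> str:
    """Region class from the annotation features the circRNA's exons overlap."""
    gene = next(g for g in genes if g.gene_id == junction.host_gene)
    tx = gene.longest_transcript()
    if not tx.cds:
        return "other"
    exons, fi, li = _span_exon_indices(junction, gene)
    circ_exons = exons[fi : li + 1]
    u5, u3 = tx.utrs(gene.strand)
    has_cds = any(_overlaps(iv, tx.cds) for iv in circ_exons)
    has_u5 = any(_overlaps(iv, u5) for iv in circ_exons)
    has_u3 = any(_overlaps(iv, u3) for iv in circ_exons)
    if has_cds and not has_u5 and not has_u3:
        return "CDS"
    if has_cds and has_u5 and not has_u3:
        return "5'UTR+CDS"
    if has_cds and has_u3 and not has_u5:
        return "3'UTR+CDS"
    if has_u5 and not has_cds and not has_u3:
        return "5'UTR"
    if has_u3 and not has_cds and not has_u5:
        return "3'UTR"
    return "other"


def catalog_summaries(
    catalog: Sequence[CircJunction], genes: Sequence[GeneModel]
) -> tuple[pd.Series, pd.DataFrame]:
    """(circRNAs per gene, per-circRNA exon count / first-exon rank table).

    The first-exon rank is 1-based from the transcript 5' end and reported
    only for circRNAs containing more than one exon.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene = pd.Series(
        [j.host_gene for j in catalog], dtype=object
    ).value_counts()
    rows = []
    for j in catalog:
        gene = gene_by_id[j.host_gene]
        exons, fi, li = _span_exon_indices(j, gene)
        n_in_circ = li - fi + 1
        if gene.strand == "+":
            rank = fi + 1
        else:
            rank = len(exons) - li
        rows.append(
            {
                "circ_id": j.circ_id,
                "gene": j.host_gene,
                "n_exons": n_in_circ,
                "first_exon_rank": rank if n_in_circ > 1 else np.nan,
                "region_class": classify_region(j, genes),
            }
        )
    return per_gene, pd.DataFrame(rows).set_index("circ_id")


# ---------------------------------------------------------------------------
# flanking introns


def flanking_introns_by_index(
    gene: GeneModel, first_idx: int, last_idx: int, genome: GenomeSequence
) -> tuple[str, str]:
    """Strand-oriented (upstream, downstream) flanking intron sequences for
    exons ``first_idx``..``last_idx`` (genomic order) of the reference
    transcript."""
    exons = gene.longest_transcript().exons
    if first_idx <= 0 or last_idx >= len(exons) - 1:
        raise FlankingIntronError(
            f"{gene.gene_id}: exon span touches a transcript terminus"
        )
    left = (exons[first_idx - 1][1], exons[first_idx][0])
    right = (exons[last_idx][1], exons[last_idx + 1][0])
    left_seq = genome.fetch(gene.chrom, *left)
    right_seq = genome.fetch(gene.chrom, *right)
    if gene.strand == "+":
        return left_seq, right_seq
    return revcomp(right_seq), revcomp(left_seq)


def extract_flanking_introns(
    junction: CircJunction, genes: Sequence[GeneModel], genome: GenomeSequence
) -> tuple[str, str]:
    gene = next(g for g in genes if g.gene_id == junction.host_gene)
    _, fi, li = _span_exon_indices(junction, gene)
    return flanking_introns_by_index(gene, fi, li, genome)


@dataclass(frozen=True)
class ControlLocus:
    """A position-matched control: one exon (by transcript rank) of a
    non-circRNA gene with flanking introns on both sides."""

    gene_id: str
    exon_rank: int
    genomic_index: int


def select_control_loci(
    genes: Sequence[GeneModel],
    circ_gene_ids: set[str],
    exon_rank: int,
    n: int,
    seed: int = 0,
) -> list[ControlLocus]:
    """Sample up to ``n`` control exons of the given transcript rank from
    genes that host no circRNA, requiring both flanking introns."""
    rng = np.random.default_rng(seed)
    eligible = []
    for g in genes:
        if g.gene_id in circ_gene_ids:
            continue
        n_ex = len(g.longest_transcript().exons)
        gi = exon_rank - 1 if g.strand == "+" else n_ex - exon_rank
        if 1 <= gi <= n_ex - 2:
            eligible.append(ControlLocus(g.gene_id, exon_rank, gi))
    if len(eligible) <= n:
        return eligible
    pick = rng.choice(len(eligible), n, replace=False)
    return [eligible[i] for i in sorted(pick)]


# ---------------------------------------------------------------------------
# RCM search


@dataclass(frozen=True)
class RCMHit:
    """One ungapped RCM: intervals on the two introns (native orientation of
    the sequences as passed), match length and score."""

    up_start: int
    up_end: int
    down_start: int
    down_end: int
    length: int
    score: int


def _extend(a: str, b: str, i: int, j: int, step: int, xdrop: int) -> tuple[int, int]:
    """Ungapped X-drop extension from (i, j) in direction ``step``.

    Returns (best score gain, its length); +1 match, -2 mismatch, stop when
    the running score falls more than ``xdrop`` below the best.
    """
    best = 0
    best_len = 0
    running = 0
    t = 0
    while 0 <= i + step * t < len(a) and 0 <= j + step * t < len(b):
        running += 1 if a[i + step * t] == b[j + step * t] else -2
        t += 1
        if running > best:
            best = running
            best_len = t
        if running < best - xdrop:
            break
    return best, best_len


def find_rcms(
    upstream: str,
    downstream: str,
    word_size: int = 7,
    min_score: int = 10,
    xdrop: int = 6,
) -> list[RCMHit]:
    """Seed-and-extend reverse-complementary matches between two introns.

    Seeds are exact ``word_size`` matches between ``upstream`` and the
    reverse complement of ``downstream``; hit coordinates on the downstream
    intron are mapped back to its native orientation.
    """
    w = word_size
    if len(upstream) < w or len(downstream) < w:
        return []
    d = revcomp(downstream)
    seeds: dict[str, list[int]] = {}
    for j in range(len(d) - w + 1):
        seeds.setdefault(d[j : j + w], []).append(j)
    found: dict[tuple[int, int, int], RCMHit] = {}
    for i in range(len(upstream) - w + 1):
        for j in seeds.get(upstream[i : i + w], ()):
            right, rlen = _extend(upstream, d, i + w, j + w, +1, xdrop)
            left, llen = _extend(upstream, d, i - 1, j - 1, -1, xdrop)
            score = w + right + left
            if score < min_score:
                continue
            us, ue = i - llen, i + w + rlen
            ds, de = j - llen, j + w + rlen
            key = (i - j, us, ue)
            if key not in found:
                found[key] = RCMHit(
                    us,
                    ue,
                    len(downstream) - de,
                    len(downstream) - ds,
                    ue - us,
                    score,
                )
    return sorted(found.values(), key=lambda h: (h.up_start, h.down_start))


# ---------------------------------------------------------------------------
# per-locus summaries and enrichment


def locus_rcm_summary(
    locus_id: str, locus_type: str, hits: Sequence[RCMHit]
) -> dict:
    return {
        "locus_id": locus_id,
        "locus_type": locus_type,
        "n_hits": len(hits),
        "max_length": max((h.length for h in hits), default=0),
        "total_score": sum(h.score for h in hits),
    }


def rcm_enrichment_test(
    summaries: pd.DataFrame, value: str = "n_hits"
) -> dict:
    """Kruskal-Wallis across locus types on a per-locus RCM statistic
    (default: hit count), with Dunn's pairwise post-hoc p-values."""
    types = list(dict.fromkeys(summaries["locus_type"]))
    if len(types) < 2:
        raise ValueError("need >= 2 locus groups")
    groups = []
    for t in types:
        g = summaries.loc[summaries["locus_type"] == t, value].to_numpy(float)
        if g.size == 0:
            raise ValueError(f"locus group {t!r} is empty")
        groups.append(g)
    h, p = kruskal_wallis(groups)
    return {
        "H": h,
        "p": p,
        "dunn": dunn(groups, labels=types),
        "group_means": {t: float(g.mean()) for t, g in zip(types, groups)},
    }
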