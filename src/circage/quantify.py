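"""Junction-read counting against templates, TPM normalization, and
per-time-point detection matrices.

Counting is template-based and independent of the discovery heuristics: a
read counts toward a circRNA iff it places on that circRNA's junction
template crossing the midpoint with at least ``min_junction_overlap`` nt on
each side, with few mismatches overall and at most one mismatch inside the
overlap window on either side of the midpoint (which keeps linear reads
that merely graze the junction from counting).  Placement is seed-based, so
reads may overhang the template ends.  PCR duplicates — fragments from one
library whose junction reads place at identical template coordinates —
count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import CircJunction
from .genome_io import LibraryMeta, PipelineConfig, revcomp
from .simulate import ReadPair


@dataclass
class CountMatrix:
    """circRNA x library deduplicated junction read counts plus library sizes."""

    values: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        missing = set(self.values.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for {sorted(missing)}")


@dataclass
class TPMMatrix:
    """Same shape as :class:`CountMatrix`; count x 1e6 / library size."""

    values: pd.DataFrame


@dataclass
class QuantStats:
    reads_counted: int = 0
    ambiguous_reads: int = 0
    ambiguous_fragments: int = 0


def library_size_series(libraries: Sequence[LibraryMeta]) -> pd.Series:
    return pd.Series(
        {m.library_id: m.total_fragments for m in libraries}, dtype=float
    )


class _TemplateIndex:
    def __init__(self, templates: Mapping[str, str], k: int):
        self.k = k
        self.templates = dict(templates)
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for cid, tmpl in templates.items():
            for i in range(len(tmpl) - k + 1):
                self.seeds.setdefault(tmpl[i : i + k], []).append((cid, i))

    def candidate_offsets(self, read: str) -> set[tuple[str, int]]:
        L = len(read)
        k = self.k
        positions = list(range(0, L - k + 1, 10))
        if positions[-1] != L - k:
            positions.append(L - k)
        out: set[tuple[str, int]] = set()
        for p in positions:
            for cid, tpos in self.seeds.get(read[p : p + k], ()):
                out.add((cid, tpos - p))
        return out


def _evaluate_placement(
    read: str, tmpl: str, off: int, cfg: PipelineConfig
) -> tuple[int, bool] | None:
    """Score a read placed at template offset ``off``.

    Returns (matched_bases, crossing_ok) or None when the placement fails
    the mismatch rules.  ``crossing_ok`` is True when the read crosses the
    template midpoint with >= min_junction_overlap aligned nt on each side.
    """
    L, T = len(read), len(tmpl)
    mid = T // 2
    lo, hi = max(0, off), min(T, off + L)
    if hi - lo < cfg.min_junction_overlap:
        return None
    seg_r = read[lo - off : hi - off]
    seg_t = tmpl[lo:hi]
    mism = sum(a != b for a, b in zip(seg_r, seg_t))
    if mism > cfg.max_mismatches:
        return None
    w = cfg.min_junction_overlap
    crossing = (mid - lo >= w) and (hi - mid >= w)
    if crossing:
        lw = sum(
            a != b
            for a, b in zip(read[mid - w - off : mid - off], tmpl[mid - w : mid])
        )
        rw = sum(
            a != b
            for a, b in zip(read[mid - off : mid + w - off], tmpl[mid : mid + w])
        )
        if lw > 1 or rw > 1:
            crossing = False
    return (hi - lo - mism, crossing)


def count_junction_reads(
    reads: Mapping[str, Sequence[ReadPair]],
    templates: Mapping[str, str],
    catalog: Sequence[CircJunction],
    libraries: Sequence[LibraryMeta],
    cfg: PipelineConfig,
    stats: QuantStats | None = None,
) -> CountMatrix:
    """Count deduplicated junction-crossing fragments per circRNA and library.

    A fragment counts toward a circRNA when at least one of its mates has a
    best-scoring, midpoint-crossing placement on that circRNA's template; a
    mate whose best score is tied between two circRNAs is assigned to
    neither, and a fragment whose mates disagree is dropped (both tallied).
    """
    stats = stats if stats is not None else QuantStats()
    index = _TemplateIndex(templates, cfg.anchor_length)
    lib_ids = [m.library_id for m in libraries]
    keys: dict[tuple[str, str], set] = {}
    for lib, pairs in reads.items():
        for pair in pairs:
            assignments: dict[str, list[tuple[int, int]]] = {}
            ambiguous = False
            for mate, raw in enumerate((pair.r1, pair.r2)):
                best_score = 0
                best: list[tuple[str, int]] = []
                for seq in (raw, revcomp(raw)):
                    for cid, off in index.candidate_offsets(seq):
                        res = _evaluate_placement(seq, templates[cid], off, cfg)
                        if res is None or not res[1]:
                            continue
                        score, _ = res
                        if score > best_score:
                            best_score = score
                            best = [(cid, off)]
                        elif score == best_score:
                            best.append((cid, off))
                if not best:
                    continue
                cids = {cid for cid, _ in best}
                if len(cids) > 1:
                    stats.ambiguous_reads += 1
                    continue
                cid, off = best[0]
                assignments.setdefault(cid, []).append((mate, off))
            if not assignments:
                continue
            if len(assignments) > 1:
                stats.ambiguous_fragments += 1
                continue
            (cid, mate_offsets), = assignments.items()
            stats.reads_counted += len(mate_offsets)
            keys.setdefault((cid, lib), set()).add(tuple(sorted(mate_offsets)))
    mat = pd.DataFrame(
        0, index=[j.circ_id for j in catalog], columns=lib_ids, dtype=int
    )
    for (cid, lib), ks in keys.items():
        if cid in mat.index and lib in mat.columns:
            mat.loc[cid, lib] = len(ks)
    return CountMatrix(mat, library_size_series(libraries))


def tpm_normalize(counts: CountMatrix) -> TPMMatrix:
    """Transcripts-per-million against total library fragments."""
    sizes = counts.library_sizes.reindex(counts.values.columns)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return TPMMatrix(counts.values * 1e6 / sizes)


def timepoint_detection(
    counts: CountMatrix,
    libraries: Sequence[LibraryMeta],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-circRNA counts summed over replicates of each time-point, and the
    boolean detection matrix at the ``min_timepoint_reads`` threshold."""
    lib_tp = {m.library_id: m.time_point for m in libraries}
    missing = [c for c in counts.values.columns if c not in lib_tp]
    if missing:
        raise ValueError(f"libraries without time-point label: {missing}")
    tps = list(dict.fromkeys(m.time_point for m in libraries))
    sums = counts.values.T.groupby([lib_tp[c] for c in counts.values.columns]).sum().T
    sums = sums[tps]
    return sums, sums >= cfg.min_timepoint_reads
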