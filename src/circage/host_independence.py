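"""Host-gene-independence analysis.

A circRNA accumulates independently of its host gene when its
circular:(circular+linear) read ratio changes across time-points.  Linear
(forward-spliced) reads are counted at the circRNA's two boundary
coordinates and averaged; replicate-level (circ, circ+linear) pairs are
then modelled as beta-binomial draws with a shared overdispersion, and a
likelihood-ratio test compares one common proportion (H0) against
per-time-point proportions (H1), with p from chi-square on T-1 degrees of
freedom and BH correction across tested circRNAs.

The overdispersion is parametrized as phi = 1/(1+theta) in [0, 1); the
boundary phi = 0 is the exact binomial likelihood, evaluated in closed
form, so the test reduces to the classical binomial LRT for
non-overdispersed data.  The fit is a profile likelihood: for each phi the
group proportions are optimized independently (bounded 1-D searches), and
phi itself is optimized by a bounded scalar search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from .detect import CircJunction
from .genome_io import (
    FragmentAlignment,
    LibraryMeta,
    PipelineConfig,
    round_half_up,
)

_PHI_MAX = 0.9


# ---------------------------------------------------------------------------
# linear junction-read counting


def count_linear_junction_reads(
    alignments: Sequence[FragmentAlignment],
    catalog: Sequence[CircJunction],
    cfg: PipelineConfig,
    libraries: Sequence[LibraryMeta] | None = None,
) -> pd.DataFrame:
    """Deduplicated forward-orientation read counts at circRNA boundaries.

    A fragment crosses a boundary coordinate x when one of its mates either
    covers [x - w, x + w) contiguously or uses x as the donor/acceptor of a
    forward splice with >= w aligned nt on each side (w =
    ``min_junction_overlap``).  Back-splice fragments are excluded.  The
    start- and end-boundary counts are averaged, rounding half up.
    """
    w = cfg.min_junction_overlap
    boundary_map: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for j in catalog:
        boundary_map.setdefault((j.chrom, j.start), []).append((j.circ_id, 0))
        boundary_map.setdefault((j.chrom, j.end), []).append((j.circ_id, 1))
    hits: dict[tuple[str, int, str], set] = {}

    def register(chrom: str, x: int, aln: FragmentAlignment) -> None:
        for cid, side in boundary_map.get((chrom, x), ()):
            hits.setdefault((cid, side, aln.library_id), set()).add(aln.outer())

    for aln in alignments:
        if aln.flag == "backsplice":
            continue
        for mate in aln.blocks:
            for bi, (s, e) in enumerate(mate):
                if bi + 1 < len(mate):
                    s2, e2 = mate[bi + 1]
                    if e - s >= w and e2 - s2 >= w:
                        register(aln.chrom, e, aln)  # donor side of the splice
                        register(aln.chrom, s2, aln)  # acceptor side
                for x in _boundaries_within(boundary_map, aln.chrom, s + w, e - w):
                    register(aln.chrom, x, aln)
    counts: dict[str, dict[str, list[int]]] = {}
    for (cid, side, lib), frags in hits.items():
        counts.setdefault(cid, {}).setdefault(lib, [0, 0])[side] = len(frags)
    lib_ids = (
        [m.library_id for m in libraries]
        if libraries is not None
        else sorted({k[2] for k in hits})
    )
    mat = pd.DataFrame(0, index=[j.circ_id for j in catalog], columns=lib_ids, dtype=int)
    for cid, per_lib in counts.items():
        for lib, (a, b) in per_lib.items():
            if lib in mat.columns:
                mat.loc[cid, lib] = round_half_up((a + b) / 2)
    return mat


def _boundaries_within(boundary_map, chrom, lo, hi):
    # boundary sets are small; linear scan is fine at this scale
    return [x for (c, x) in boundary_map if c == chrom and lo <= x <= hi]


# ---------------------------------------------------------------------------
# beta-binomial likelihood machinery


def _bb_loglik(c: np.ndarray, n: np.ndarray, pi: float, phi: float) -> float:
    """Beta-binomial log-likelihood; phi = 0 is the exact binomial limit."""
    if pi <= 0.0 or pi >= 1.0:
        return -np.inf
    if phi <= 0.0:
        return float(
            np.sum(
                gammaln(n + 1)
                - gammaln(c + 1)
                - gammaln(n - c + 1)
                + xlogy(c, pi)
                + xlogy(n - c, 1.0 - pi)
            )
        )
    theta = (1.0 - phi) / phi
    a = pi * theta
    b = (1.0 - pi) * theta
    return float(
        np.sum(
            gammaln(n + 1)
            - gammaln(c + 1)
            - gammaln(n - c + 1)
            + gammaln(c + a)
            + gammaln(n - c + b)
            - gammaln(n + a + b)
            + gammaln(a + b)
            - gammaln(a)
            - gammaln(b)
        )
    )


def _best_pi(c: np.ndarray, n: np.ndarray, phi: float, xatol: float = 1e-10) -> float:
    """Profile the proportion at fixed overdispersion (bounded 1-D search)."""
    if phi <= 0.0:
        return float(np.clip(c.sum() / n.sum(), 1e-9, 1 - 1e-9))
    res = optimize.minimize_scalar(
        lambda p: -_bb_loglik(c, n, p, phi),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x)


def _profile_loglik(
    groups: list[tuple[np.ndarray, np.ndarray]], phi: float, xatol: float = 1e-10
) -> float:
    return sum(_bb_loglik(c, n, _best_pi(c, n, phi, xatol), phi) for c, n in groups)


# dense near zero: the profile optimum often sits just off the binomial
# boundary, and missing it biases the LRT
_PHI_GRID = np.array(
    [0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 0.05, 0.15, 0.4, _PHI_MAX]
)


def _fit(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Maximize the profile likelihood over shared phi; returns (ll, phi).

    The binomial boundary phi = 0 is evaluated in closed form; a coarse grid
    locates the profile optimum and a bounded scalar search refines it only
    when positive overdispersion actually improves the likelihood, so
    non-overdispersed data take the fast exact path.
    """
    coarse = [
        _profile_loglik(groups, phi, xatol=1e-7) for phi in _PHI_GRID
    ]
    best_i = int(np.argmax(coarse))
    ll_bin = coarse[0]
    if best_i == 0 or coarse[best_i] <= ll_bin + 1e-9:
        return ll_bin, 0.0
    lo = _PHI_GRID[max(best_i - 1, 0)] or 1e-8
    hi = _PHI_GRID[min(best_i + 1, len(_PHI_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda f: -_profile_loglik(groups, f),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun > ll_bin:
        return float(-res.fun), float(res.x)
    return ll_bin, 0.0


@dataclass
class RatioTestFit:
    loglik_h0: float
    loglik_h1: float
    phi_h0: float
    phi_h1: float
    lrt: float
    df: int
    p: float


def betabinomial_lrt(
    circ: np.ndarray, total: np.ndarray, group_labels: np.ndarray
) -> RatioTestFit:
    """LRT of a common circ:(circ+linear) proportion against per-group
    proportions, shared overdispersion under each hypothesis."""
    circ = np.asarray(circ, dtype=float)
    total = np.asarray(total, dtype=float)
    keep = total > 0
    circ, total, group_labels = circ[keep], total[keep], np.asarray(group_labels)[keep]
    if circ.size == 0:
        raise ValueError("no replicate with circ+linear > 0")
    uniq = list(dict.fromkeys(group_labels.tolist()))
    groups = [
        (circ[group_labels == g], total[group_labels == g]) for g in uniq
    ]
    ll0, phi0 = _fit([(circ, total)])
    ll1, phi1 = _fit(groups)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    df = len(uniq) - 1
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    return RatioTestFit(ll0, ll1, phi0, phi1, lrt, df, min(max(p, 1e-300), 1.0))


# ---------------------------------------------------------------------------
# the ratio test across a catalog


def circ_host_ratio_test(
    circ_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    libraries: Sequence[LibraryMeta],
    cfg: PipelineConfig,
    time_points: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Host-independence test for every eligible circRNA.

    Eligibility follows the detection rule: summed circular reads >=
    ``min_timepoint_reads`` in every compared time-point.  Returns per-circ
    per-time-point circular/linear sums and ratios, the LRT p, BH q and the
    ``independent`` call at (alpha, fdr_threshold_ratio).
    """
    lib_tp = {m.library_id: m.time_point for m in libraries}
    tps = list(time_points) if time_points else list(
        dict.fromkeys(m.time_point for m in libraries)
    )
    cols = [c for c in circ_counts.columns if lib_tp.get(c) in tps]
    labels = np.array([lib_tp[c] for c in cols])
    rows = []
    for cid in circ_counts.index:
        c = circ_counts.loc[cid, cols].to_numpy(float)
        l = linear_counts.loc[cid, cols].to_numpy(float) if cid in linear_counts.index else np.zeros(len(cols))
        tp_circ = {tp: c[labels == tp].sum() for tp in tps}
        if any(tp_circ[tp] < cfg.min_timepoint_reads for tp in tps):
            continue
        total = c + l
        if not (total > 0).any():
            continue
        fit = betabinomial_lrt(c, total, labels)
        row = {"circ_id": cid, "p": fit.p, "lrt": fit.lrt, "phi": fit.phi_h1}
        for tp in tps:
            cs = tp_circ[tp]
            ls = l[labels == tp].sum()
            row[f"circ_{tp}"] = cs
            row[f"linear_{tp}"] = ls
            row[f"ratio_{tp}"] = cs / (cs + ls) if cs + ls > 0 else np.nan
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["circ_id", "p", "q", "independent"]
        ).set_index("circ_id")
    out = pd.DataFrame(rows).set_index("circ_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["independent"] = (out["p"] < cfg.alpha) & (out["q"] < cfg.fdr_threshold_ratio)
    return out


def classify_independent_changes(
    results: pd.DataFrame,
    circ_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    libraries: Sequence[LibraryMeta],
    pair: tuple[str, str],
    cfg: PipelineConfig,
) -> dict:
    """Direction of host-independent changes for one (old, young) pair, plus
    the (circ log2FC, linear log2FC) pairs and their Pearson correlation
    over all tested circRNAs (the density-plot statistics)."""
    old, young = pair
    lib_tp = {m.library_id: m.time_point for m in libraries}
    co = [c for c in circ_counts.columns if lib_tp.get(c) == old]
    cy = [c for c in circ_counts.columns if lib_tp.get(c) == young]

    def log2fc(df: pd.DataFrame, idx) -> pd.Series:
        so = df.loc[idx, co].sum(axis=1).astype(float)
        sy = df.loc[idx, cy].sum(axis=1).astype(float)
        need = (so == 0) | (sy == 0)
        return np.log2((so + 0.5 * need) / (sy + 0.5 * need))

    tested = results.index
    circ_fc = log2fc(circ_counts, tested)
    lin_fc = log2fc(linear_counts.reindex(circ_counts.index).fillna(0), tested)
    indep = results["independent"]
    n_up = int(((circ_fc > 0) & indep).sum())
    n_down = int(((circ_fc < 0) & indep).sum())
    if len(tested) >= 2 and circ_fc.std() > 0 and lin_fc.std() > 0:
        r = float(stats.pearsonr(circ_fc, lin_fc)[0])
    else:
        r = np.nan
    density = pd.DataFrame(
        {"circ_log2fc": circ_fc, "linear_log2fc": lin_fc, "independent": indep}
    )
    return {"n_up": n_up, "n_down": n_down, "pearson_r": r, "density": density}
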