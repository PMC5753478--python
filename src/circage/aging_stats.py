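"""Differential age-accumulation statistics on circRNA TPM values.

Pairwise comparisons between time-points use fold changes of mean TPM and
unpaired Welch t-tests with Benjamini-Hochberg FDR within each comparison;
a circRNA is called up when FC > fc_threshold, P < alpha and q <
fdr_threshold_diff (down symmetrically).  Global trends use Kruskal-Wallis
across all time-points with the Nemenyi post-hoc, age-specific circRNAs
come from the per-time-point 6-read detection rule, and PCA on the
centered TPM matrix serves as clustering QC.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genome_io import LibraryMeta, PipelineConfig
from .quantify import TPMMatrix
from .rank_tests import kruskal_wallis, nemenyi


def _group_columns(
    libraries: Sequence[LibraryMeta], tpm: pd.DataFrame, time_point: str
) -> list[str]:
    cols = [
        m.library_id
        for m in libraries
        if m.time_point == time_point and m.library_id in tpm.columns
    ]
    if not cols:
        raise ValueError(f"unknown or absent time-point {time_point!r}")
    return cols


def pairwise_fold_changes(
    tpm: TPMMatrix,
    libraries: Sequence[LibraryMeta],
    pair: tuple[str, str],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """log2 fold change of mean TPM, old over young, per circRNA.

    ``pair`` is (old, young).  When either group mean is zero a pseudocount
    equal to the smallest nonzero TPM within the comparison is added to both
    means.  Also returns the fractions of circRNAs at or beyond the
    fc_threshold in each direction.
    """
    old, young = pair
    mo = tpm.values[_group_columns(libraries, tpm.values, old)].mean(axis=1)
    my = tpm.values[_group_columns(libraries, tpm.values, young)].mean(axis=1)
    sub = tpm.values[
        _group_columns(libraries, tpm.values, old)
        + _group_columns(libraries, tpm.values, young)
    ].to_numpy()
    nonzero = sub[sub > 0]
    eps = float(nonzero.min()) if nonzero.size else 1.0
    need = (mo == 0) | (my == 0)
    fc = (mo + need * eps) / (my + need * eps)
    df = pd.DataFrame(
        {
            "mean_old": mo,
            "mean_young": my,
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )
    summary = {
        "frac_up": float((fc >= cfg.fc_threshold).mean()) if len(fc) else 0.0,
        "frac_down": float((fc <= 1 / cfg.fc_threshold).mean()) if len(fc) else 0.0,
        "pseudocount": eps,
    }
    return df, summary


def pairwise_ttests(
    tpm: TPMMatrix,
    libraries: Sequence[LibraryMeta],
    pair: tuple[str, str],
    cfg: PipelineConfig,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-circRNA unpaired t-tests (Welch by default) with BH correction.

    Returns one row per circRNA: group means, log2FC, p, BH q and the call
    in {'up', 'down', 'ns'}.  Zero variance in both groups with equal means
    yields p = 1 and is flagged in the ``degenerate`` column.
    """
    old, young = pair
    co = _group_columns(libraries, tpm.values, old)
    cy = _group_columns(libraries, tpm.values, young)
    if min(len(co), len(cy)) < 2:
        raise ValueError("each time-point needs >= 2 replicates")
    a = tpm.values[co].to_numpy(float)
    b = tpm.values[cy].to_numpy(float)
    with np.errstate(all="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    fc_df, _ = pairwise_fold_changes(tpm, libraries, pair, cfg)
    fc = fc_df["fc"].to_numpy()
    up = (fc > cfg.fc_threshold) & (p < cfg.alpha) & (q < cfg.fdr_threshold_diff)
    down = (fc < 1 / cfg.fc_threshold) & (p < cfg.alpha) & (q < cfg.fdr_threshold_diff)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    return pd.DataFrame(
        {
            "comparison": f"{old}_vs_{young}",
            "mean_old": fc_df["mean_old"],
            "mean_young": fc_df["mean_young"],
            "log2fc": fc_df["log2fc"],
            "p": p,
            "q": q,
            "call": call,
            "degenerate": degenerate,
        },
        index=tpm.values.index,
    )


def global_kw_nemenyi(
    tpm: TPMMatrix, libraries: Sequence[LibraryMeta]
) -> dict:
    """Kruskal-Wallis on pooled per-circRNA TPM values grouped by time-point,
    with Nemenyi pairwise post-hoc p-values."""
    tps = list(dict.fromkeys(m.time_point for m in libraries))
    if len(tps) < 3:
        raise ValueError("need >= 3 time-points for the global test")
    groups = [
        tpm.values[_group_columns(libraries, tpm.values, tp)].to_numpy().ravel()
        for tp in tps
    ]
    h, p = kruskal_wallis(groups)
    return {"H": h, "p": p, "nemenyi": nemenyi(groups, labels=tps)}


def age_specific_circrnas(
    timepoint_sums: pd.DataFrame,
    cfg: PipelineConfig,
    strict: bool = True,
) -> dict[str, list[str]]:
    """circRNAs passing the read threshold at exactly one time-point.

    ``strict`` requires zero reads at every other time-point; otherwise
    other time-points only need to stay below ``min_timepoint_reads``.
    """
    out: dict[str, list[str]] = {tp: [] for tp in timepoint_sums.columns}
    thr = cfg.min_timepoint_reads
    for cid, row in timepoint_sums.iterrows():
        passing = row[row >= thr]
        if len(passing) != 1:
            continue
        tp = passing.index[0]
        others = row.drop(tp)
        if strict and (others > 0).any():
            continue
        out[tp].append(cid)
    return out


def pca_qc(tpm: TPMMatrix, libraries: Sequence[LibraryMeta], log: bool = False):
    """Project libraries on the first two principal components of the
    centered circRNA-TPM matrix; returns (scores, variance_explained)."""
    x = tpm.values.to_numpy(float).T  # libraries x circRNAs
    if x.shape[0] < 2:
        raise ValueError("need >= 2 libraries")
    if log:
        x = np.log2(x + 1)
    if np.allclose(x, x[0]):
        raise ValueError("no variance in TPM matrix")
    n_comp = min(2, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    score_df = pd.DataFrame(
        scores,
        index=tpm.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    tp_map = {m.library_id: m.time_point for m in libraries}
    score_df["time_point"] = [tp_map.get(c, "") for c in score_df.index]
    return score_df, pca.explained_variance_ratio_
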