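import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circage import aging_stats, quantify, simulate
from circage.genome_io import LibraryMeta, PipelineConfig
from circage.quantify import CountMatrix, TPMMatrix, library_size_series
from circage.rank_tests import dunn, kruskal_wallis, nemenyi


def _libs(tps=("L4", "D1", "D7", "D10"), reps=3):
    return [
        LibraryMeta(f"{tp}_r{r}", tp, r, 1_000_000)
        for tp in tps
        for r in range(1, reps + 1)
    ]


def _tpm(values: dict, index) -> TPMMatrix:
    return TPMMatrix(pd.DataFrame(values, index=index, dtype=float))


# ---------------------------------------------------------------------------
# fold changes


def test_fold_change_arithmetic(pcfg):
    libs = _libs(("D10", "L4"))
    tpm = _tpm(
        {
            "D10_r1": [30, 5],
            "D10_r2": [30, 5],
            "D10_r3": [30, 5],
            "L4_r1": [10, 5],
            "L4_r2": [10, 5],
            "L4_r3": [10, 5],
        },
        ["c1", "c2"],
    )
    df, summary = aging_stats.pairwise_fold_changes(tpm, libs, ("D10", "L4"), pcfg)
    assert df.loc["c1", "log2fc"] == pytest.approx(np.log2(3))
    assert df.loc["c2", "log2fc"] == 0.0
    assert summary["frac_up"] == 0.5


def test_fold_change_pseudocount_on_zero_means(pcfg):
    libs = _libs(("D10", "L4"))
    tpm = _tpm(
        {
            "D10_r1": [8.0],
            "D10_r2": [8.0],
            "D10_r3": [8.0],
            "L4_r1": [0.0],
            "L4_r2": [0.0],
            "L4_r3": [0.0],
        },
        ["c1"],
    )
    df, summary = aging_stats.pairwise_fold_changes(tpm, libs, ("D10", "L4"), pcfg)
    # pseudocount = smallest nonzero TPM in the comparison = 8
    assert summary["pseudocount"] == 8.0
    assert df.loc["c1", "fc"] == pytest.approx(16.0 / 8.0)


def test_fold_change_unknown_timepoint_errors(pcfg):
    libs = _libs(("D10", "L4"))
    tpm = _tpm({m.library_id: [1.0] for m in libs}, ["c1"])
    with pytest.raises(ValueError):
        aging_stats.pairwise_fold_changes(tpm, libs, ("D3", "L4"), pcfg)


# ---------------------------------------------------------------------------
# BH correction: brute-force oracle


def _bh_oracle(p):
    """q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j (sorted ranks)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(m * p[order[k]] / (k + 1) for k in range(pos, m))
    return np.minimum(q, 1.0)


@given(
    st.lists(
        st.sampled_from([round(0.001 * k, 3) for k in range(1, 1000)]),
        min_size=1,
        max_size=6,
    )
)
def test_bh_matches_brute_force_min_formula(pvec):
    p = np.asarray(pvec, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, _bh_oracle(p), atol=1e-12)


def test_bh_worked_example():
    q = multipletests([0.005, 0.01, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])


# ---------------------------------------------------------------------------
# t-tests


def test_ttest_identical_groups_is_ns(pcfg):
    libs = _libs(("D10", "L4"))
    tpm = _tpm(
        {
            "D10_r1": [1.0],
            "D10_r2": [2.0],
            "D10_r3": [3.0],
            "L4_r1": [1.0],
            "L4_r2": [2.0],
            "L4_r3": [3.0],
        },
        ["c1"],
    )
    res = aging_stats.pairwise_ttests(tpm, libs, ("D10", "L4"), pcfg)
    assert res.loc["c1", "p"] == pytest.approx(1.0)
    assert res.loc["c1", "call"] == "ns"


def test_ttest_zero_variance_flagged(pcfg):
    libs = _libs(("D10", "L4"))
    tpm = _tpm({m.library_id: [5.0] for m in libs}, ["c1"])
    res = aging_stats.pairwise_ttests(tpm, libs, ("D10", "L4"), pcfg)
    assert res.loc["c1", "p"] == 1.0
    assert bool(res.loc["c1", "degenerate"])


def test_calls_monotone_in_thresholds(pcfg):
    rng = np.random.default_rng(0)
    libs = _libs(("D10", "L4"))
    values = {
        m.library_id: rng.gamma(2, 10, 50) * (3 if m.time_point == "D10" else 1)
        for m in libs
    }
    tpm = _tpm(values, [f"c{i}" for i in range(50)])
    strict = aging_stats.pairwise_ttests(tpm, libs, ("D10", "L4"), pcfg)
    loose_cfg = PipelineConfig(fc_threshold=1.1, fdr_threshold_diff=0.5)
    loose = aging_stats.pairwise_ttests(tpm, libs, ("D10", "L4"), loose_cfg)
    called_strict = set(strict.index[strict["call"] != "ns"])
    called_loose = set(loose.index[loose["call"] != "ns"])
    assert called_strict <= called_loose


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Nemenyi


def test_kw_hand_fixture_matches_rank_formula():
    groups = [np.array([1, 2]), np.array([3, 4]), np.array([5, 6])]
    h, p = kruskal_wallis(groups)
    # ranks 1..6, mean ranks 1.5/3.5/5.5: H = 12/(6*7)*2*sum(R^2) - 3*7
    expected = 12 / 42 * 2 * (1.5**2 + 3.5**2 + 5.5**2) - 21
    assert h == pytest.approx(expected)
    assert h == pytest.approx(4.571428571)


@given(st.integers(0, 10_000))
def test_kw_matches_brute_force_rank_computation(seed):
    rng = np.random.default_rng(seed)
    sizes = rng.integers(3, 8, size=3)
    groups = [rng.integers(0, 12, size=s).astype(float) for s in sizes]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        assert kruskal_wallis(groups) == (0.0, 1.0)
        return
    h, _ = kruskal_wallis(groups)
    # brute-force H with tie correction
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    i = 0
    hh = 0.0
    for g in groups:
        r = ranks[i : i + len(g)]
        hh += r.sum() ** 2 / len(g)
        i += len(g)
    hh = 12.0 / (n * (n + 1)) * hh - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    hh /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
    assert h == pytest.approx(hh)


def test_kw_identical_groups_p_one():
    groups = [np.ones(4), np.ones(4), np.ones(4)]
    assert kruskal_wallis(groups) == (0.0, 1.0)


def test_nemenyi_matrix_shape_and_symmetry():
    rng = np.random.default_rng(1)
    groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 3)]
    m = nemenyi(groups, labels=["a", "b", "c"])
    assert np.allclose(m, m.T)
    assert np.all(np.diag(m) == 1.0)
    assert m.loc["a", "c"] < m.loc["a", "b"]


def test_dunn_two_groups_equals_rank_sum_z():
    a = np.array([1.0, 3.0, 5.0, 7.0])
    b = np.array([2.0, 4.0, 6.0, 8.0])
    res = dunn([a, b], labels=["a", "b"], p_adjust=None)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    z = abs(ranks[:4].mean() - ranks[4:].mean()) / np.sqrt(
        (n * (n + 1) / 12) * (1 / 4 + 1 / 4)
    )
    assert res.loc["a", "b"] == pytest.approx(2 * stats.norm.sf(z))


def test_global_test_orders_pairs_by_age_distance(pcfg):
    cfg = simulate.SimConfig(base_circ_mean=30.0, rng_seed=4)
    circ, _, libs = simulate.simulate_counts(cfg, n_circ=60)
    tpm = quantify.tpm_normalize(CountMatrix(circ, library_size_series(libs)))
    out = aging_stats.global_kw_nemenyi(tpm, libs)
    assert out["p"] < 1e-10
    nem = out["nemenyi"]
    # distant ages separate at least as strongly as adjacent ones
    assert nem.loc["L4", "D10"] <= nem.loc["L4", "D1"]
    assert nem.loc["L4", "D7"] <= nem.loc["D7", "D10"]


# ---------------------------------------------------------------------------
# age-specific circRNAs


def test_age_specific_rules(pcfg):
    sums = pd.DataFrame(
        {
            "L4": [0, 6, 0, 3],
            "D1": [0, 6, 0, 2],
            "D7": [7, 0, 5, 0],
            "D10": [0, 0, 0, 9],
        },
        index=["c1", "c2", "c3", "c4"],
    )
    strict = aging_stats.age_specific_circrnas(sums, pcfg, strict=True)
    assert strict == {"L4": [], "D1": [], "D7": ["c1"], "D10": []}
    lenient = aging_stats.age_specific_circrnas(sums, pcfg, strict=False)
    assert lenient["D10"] == ["c4"] and lenient["D7"] == ["c1"]


def test_age_specific_recovers_planted_single_timepoint_loci(pcfg):
    cfg = simulate.SimConfig(
        base_circ_mean=30.0, age_multipliers=(0, 0, 0, 1), rng_seed=6
    )
    circ, _, libs = simulate.simulate_counts(cfg, n_circ=5)
    counts = CountMatrix(circ, library_size_series(libs))
    sums, _ = quantify.timepoint_detection(counts, libs, pcfg)
    out = aging_stats.age_specific_circrnas(sums, pcfg)
    assert sorted(out["D10"]) == sorted(circ.index)
    assert out["L4"] == out["D1"] == out["D7"] == []


# ---------------------------------------------------------------------------
# PCA QC


def test_pca_duplicate_libraries_have_identical_scores():
    rng = np.random.default_rng(2)
    col = rng.gamma(2, 10, 30)
    libs = _libs(("L4", "D10"), reps=2)
    values = {
        "L4_r1": col,
        "L4_r2": col,
        "D10_r1": col * 4,
        "D10_r2": col * 4,
    }
    tpm = _tpm(values, [f"c{i}" for i in range(30)])
    scores, var = aging_stats.pca_qc(tpm, libs)
    assert np.allclose(
        scores.loc["L4_r1", ["PC1", "PC2"]].to_numpy(float),
        scores.loc["L4_r2", ["PC1", "PC2"]].to_numpy(float),
    )
    assert var.sum() <= 1.0 + 1e-9


def test_pca_separates_young_from_old(pcfg):
    cfg = simulate.SimConfig(base_circ_mean=30.0, rng_seed=8)
    circ, _, libs = simulate.simulate_counts(cfg, n_circ=100)
    tpm = quantify.tpm_normalize(CountMatrix(circ, library_size_series(libs)))
    scores, _ = aging_stats.pca_qc(tpm, libs)
    young = scores.loc[scores["time_point"].isin(["L4", "D1"]), "PC1"]
    old = scores.loc[scores["time_point"].isin(["D7", "D10"]), "PC1"]
    within = max(young.max() - young.min(), old.max() - old.min())
    between = abs(young.mean() - old.mean())
    assert between > within


def test_pca_constant_matrix_errors():
    libs = _libs(("L4", "D10"), reps=1)
    tpm = _tpm({"L4_r1": [1.0, 1.0], "D10_r1": [1.0, 1.0]}, ["c1", "c2"])
    with pytest.raises(ValueError, match="variance"):
        aging_stats.pca_qc(tpm, libs)
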