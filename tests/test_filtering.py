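"""Filter behavior against brute-force oracles and hand-binned examples."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicox import (
    FilterConfig,
    OmicsMatrix,
    SurvivalData,
    cna_survival_filter,
    correlation_filter,
    filter_source,
    mutation_frequency_filter,
    quantization_filter,
)
from omicox.io import ValidationError

from conftest import random_survival


def matrix(source, rows, features=None, patients=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    features = features or [f"f{i}" for i in range(rows.shape[0])]
    patients = patients or [f"p{j}" for j in range(rows.shape[1])]
    return OmicsMatrix(source, pd.DataFrame(rows, index=features, columns=patients))


# ---------------------------------------------------------------------------
# correlation filter


def test_identical_features_are_kept(rng):
    x = rng.standard_normal(30)
    m = matrix("EXPR", [x, x, rng.standard_normal(30) * 100])
    kept = correlation_filter(m, 0.6)
    assert "f0" in kept and "f1" in kept


def test_independent_noise_is_dropped(rng):
    m = matrix("EXPR", rng.standard_normal((5, 200)))
    ranks = np.apply_along_axis(stats.rankdata, 1, m.values)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 0)
    assert np.abs(rho).max() <= 0.6  # construction check
    assert correlation_filter(m, 0.6) == []


@pytest.mark.parametrize("seed", range(5))
def test_correlation_filter_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(10)
    rows = [
        base,
        base + 0.1 * rng.standard_normal(10),
        rng.standard_normal(10),
        -base + 0.2 * rng.standard_normal(10),
        rng.standard_normal(10),
    ]
    m = matrix("EXPR", rows)
    kept = correlation_filter(m, 0.6)
    oracle = []
    for i in range(5):
        best = max(
            abs(stats.spearmanr(rows[i], rows[j]).statistic)
            for j in range(5)
            if j != i
        )
        if best > 0.6:
            oracle.append(f"f{i}")
    assert kept == oracle


def test_correlation_filter_order_invariant(rng):
    rows = rng.standard_normal((6, 40))
    rows[1] = rows[0] + 0.01 * rng.standard_normal(40)
    m = matrix("EXPR", rows)
    kept = set(correlation_filter(m, 0.6))
    perm = [3, 0, 5, 2, 4, 1]
    m2 = OmicsMatrix("EXPR", m.df.iloc[perm])
    kept2 = set(correlation_filter(m2, 0.6))
    assert kept == kept2


def test_correlation_filter_needs_two_features():
    with pytest.raises(ValidationError):
        correlation_filter(matrix("EXPR", [[1.0, 2.0, 3.0]]), 0.6)


# ---------------------------------------------------------------------------
# quantization filter


def test_quantization_hand_examples():
    m = matrix(
        "EXPR",
        [
            [5.0, 5.0, 5.0, 5.0, 5.0],  # constant -> dropped
            [0.0, 0.0, 0.0, 0.0, 10.0],  # 2 occupied bins -> dropped
            [0.0, 2.5, 5.0, 7.5, 10.0],  # 5 occupied bins -> kept
        ],
        features=["const", "spike", "uniform"],
    )
    assert quantization_filter(m, n_bins=5, min_occupied_bins=3) == ["uniform"]


def test_quantization_filter_uses_per_feature_range():
    # same shape, different scales: binning is per feature so both are kept
    m = matrix("MIRNA", [[0.0, 1.0, 2.0, 3.0, 4.0], [0.0, 100.0, 200.0, 300.0, 400.0]])
    assert quantization_filter(m, 5, 3) == ["f0", "f1"]


# ---------------------------------------------------------------------------
# CNA survival filter


def _planted_cna(rng, n=60, p=20):
    sv = random_survival(rng, n, censor_frac=0.3)
    rows = rng.standard_normal((p, n))
    risk = -np.log(sv.time)  # strongly prognostic covariate
    rows[7] = risk + 0.1 * rng.standard_normal(n)
    return matrix("CNA", rows), sv


def test_cna_filter_keeps_all_at_fraction_one(rng):
    m, sv = _planted_cna(rng)
    assert set(cna_survival_filter(m, sv, 1.0)) == set(m.feature_ids)


def test_cna_filter_finds_planted_feature(rng):
    m, sv = _planted_cna(rng)
    kept = cna_survival_filter(m, sv, 0.05)  # ceil(0.05*20) = 1 feature
    assert kept == ["f7"]


def test_cna_filter_ranking_matches_per_feature_oracle(rng):
    """Ranking equals an independent per-feature recomputation with
    lifelines (univariate Cox, median split, log-rank)."""
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    m, sv = _planted_cna(rng, n=50, p=12)
    _, stats_df = cna_survival_filter(m, sv, 1.0, return_stats=True)
    oracle = {}
    for fid in m.feature_ids:
        df = pd.DataFrame({"x": m.df.loc[fid], "T": sv.time, "E": sv.event})
        cph = CoxPHFitter().fit(df, "T", "E")
        pi = df["x"] * cph.params_["x"]
        high = pi > pi.median()
        res = logrank_test(
            sv.time[~high], sv.time[high],
            event_observed_A=sv.event[~high], event_observed_B=sv.event[high],
        )
        oracle[fid] = res.p_value
    oracle_order = sorted(m.feature_ids, key=lambda f: (oracle[f], f))
    assert list(stats_df.index) == oracle_order
    assert np.allclose(
        stats_df["logrank_p"].to_numpy(),
        [oracle[f] for f in stats_df.index],
        rtol=1e-6,
    )


def test_cna_filter_planted_beats_null_across_seeds():
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sv = random_survival(rng, 60, censor_frac=0.3)
        planted = -np.log(sv.time) + 0.3 * rng.standard_normal(60)
        null = rng.standard_normal(60)
        m = matrix("CNA", [planted, null], features=["planted", "null"])
        _, s = cna_survival_filter(m, sv, 1.0, return_stats=True)
        wins += s.loc["planted", "logrank_p"] < s.loc["null", "logrank_p"]
    assert wins >= 95


# ---------------------------------------------------------------------------
# mutation filter


def _mut(rows, features):
    return OmicsMatrix(
        "MUT",
        pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=features,
            columns=[f"p{j}" for j in range(np.asarray(rows).shape[1])],
        ),
    )


def test_mut_filter_prefers_frequent_genes():
    m = _mut([[1, 1, 1, 1], [0, 0, 0, 0]], ["always", "never"])
    assert mutation_frequency_filter(m, 0.5) == ["always"]


def test_mut_filter_tie_rule():
    # counts (5,3,3,1): top half = count-5 gene + lexicographically first tie
    rows = np.zeros((4, 5))
    rows[0, :5] = 1
    rows[1, :3] = 1
    rows[2, :3] = 1
    rows[3, :1] = 1
    m = _mut(rows, ["gD", "gC", "gB", "gA"])
    assert mutation_frequency_filter(m, 0.5) == ["gD", "gB"]


def test_mut_filter_keeps_all_at_fraction_one():
    rows = np.eye(3)
    m = _mut(rows, ["a", "b", "c"])
    assert set(mutation_frequency_filter(m, 1.0)) == {"a", "b", "c"}


def test_mut_filter_warns_on_all_zero():
    m = _mut(np.zeros((2, 3)), ["a", "b"])
    with pytest.warns(UserWarning):
        assert mutation_frequency_filter(m, 0.5) == []


# ---------------------------------------------------------------------------
# pipeline determinism


def test_filter_source_deterministic(cohort):
    cfg = FilterConfig(mut_top_fraction=0.3)
    for source in ("EXPR", "CNA", "MUT"):
        a = filter_source(cohort.matrices[source], cohort.survival, cfg)
        b = filter_source(cohort.matrices[source], cohort.survival, cfg)
        assert a.feature_ids == b.feature_ids
        assert set(a.feature_ids) <= set(cohort.matrices[source].feature_ids)
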