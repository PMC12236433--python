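"""Unit and property tests for the statistical primitives.

scipy.stats and statsmodels serve as independent oracles; tiny-sample
permutation nulls are enumerated here by brute force.
"""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from eddyomics.stats import (
    benjamini_hochberg,
    kruskal_wallis,
    kruskal_wallis_table,
    median_of_ratios_size_factors,
    nb_wald_matrix,
    nb_wald_two_group,
    pearson,
)

# ---------------------------------------------------------------------------
# Pearson


@pytest.mark.parametrize(
    "x,y,r_expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # sum(dx*dy)/sqrt(sum dx^2 * sum dy^2) = 4/5
    ],
)
def test_pearson_known_values(x, y, r_expected):
    res = pearson(np.array(x, float), np.array(y, float))
    assert res.statistic == pytest.approx(r_expected, abs=1e-12)


def test_pearson_matches_scipy():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(2, 25))
    mine = pearson(x, y)
    ref = sps.pearsonr(x, y)
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


@pytest.mark.parametrize("bad", [([1, 1, 1], [1, 2, 3]), ([1, 2], [3, 4])])
def test_pearson_rejects_degenerate_input(bad):
    with pytest.raises(ValueError):
        pearson(np.array(bad[0], float), np.array(bad[1], float))


@given(
    st.lists(st.floats(-100, 100), min_size=5, max_size=20),
    st.floats(0.1, 10),
    st.floats(-5, 5),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pearson_affine_invariance_and_symmetry(xs, slope, intercept):
    rng = np.random.default_rng(42)
    x = np.array(xs)
    y = x + rng.normal(0, 1, x.size)  # correlated but non-degenerate
    if np.var(x) == 0 or np.var(y) == 0:
        return
    r = pearson(x, y).statistic
    assert pearson(y, x).statistic == pytest.approx(r, abs=1e-10)
    assert pearson(slope * x + intercept, y).statistic == pytest.approx(r, abs=1e-8)
    assert pearson(-slope * x + intercept, y).statistic == pytest.approx(-r, abs=1e-8)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kruskal_wallis_no_tie_example():
    # ranks 1..6, R1=6, R2=15: H = 12/42*(12+75) - 21 = 27/7
    res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
    assert res.statistic == pytest.approx(3.857, abs=5e-4)
    assert res.p_value == pytest.approx(0.0495, abs=5e-4)


def test_kruskal_wallis_tie_correction_example():
    # midranks (1.5,1.5) vs (3.5,3.5): uncorrected 2.4, divisor 1-12/60=0.8
    res = kruskal_wallis([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
    assert res.statistic == pytest.approx(3.0, abs=1e-9)


def test_kruskal_wallis_identical_values():
    res = kruskal_wallis([np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0, 5.0])])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_wallis_rejects_single_group():
    with pytest.raises(ValueError):
        kruskal_wallis([np.array([1.0, 2.0])])


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(1)
    groups = [rng.integers(0, 5, size=n).astype(float) for n in (6, 8, 5)]
    mine = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_kruskal_wallis_monotone_transform_invariance():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=8), rng.normal(size=7)
    base = kruskal_wallis([a, b])
    for f in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
        t = kruskal_wallis([f(a), f(b)])
        assert t.statistic == pytest.approx(base.statistic, abs=1e-9)


def test_kruskal_wallis_exact_matches_brute_force_enumeration():
    a, b = np.array([1.2, 3.4, 0.1]), np.array([5.0, 6.1, 2.2, 7.0])
    res = kruskal_wallis([a, b], exact=True)
    # independent enumeration of all C(7,3) splits of the pooled ranks
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    N, n1 = 7, 3

    def h_of(r1, r2):
        h = 12 / (N * (N + 1)) * (sum(r1) ** 2 / n1 + sum(r2) ** 2 / (N - n1)) - 3 * (N + 1)
        return h

    h_obs = h_of(ranks[:3], ranks[3:])
    count = sum(
        h_of([ranks[i] for i in c], [ranks[i] for i in range(N) if i not in c]) >= h_obs - 1e-12
        for c in combinations(range(N), n1)
    )
    assert res.p_value == pytest.approx(count / 35)


def test_vectorized_kruskal_wallis_matches_scalar():
    rng = np.random.default_rng(3)
    mat = rng.integers(0, 20, size=(40, 14)).astype(float)
    h, p = kruskal_wallis_table(mat, list(range(6)), list(range(6, 14)))
    for i in range(40):
        ref = kruskal_wallis([mat[i, :6], mat[i, 6:]])
        assert h[i] == pytest.approx(ref.statistic, abs=1e-9)
        assert p[i] == pytest.approx(ref.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.04, 0.03], [0.015, 0.04, 0.04]),
    ],
)
def test_bh_step_up_known_vectors(p, expected):
    np.testing.assert_allclose(benjamini_hochberg(np.array(p)).adjusted, expected, atol=1e-12)


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(4)
    p = rng.uniform(size=200)
    mine = benjamini_hochberg(p).adjusted
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(mine, ref, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg(np.array([0.5, 1.2]))


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bh_adjusted_dominates_raw_and_is_monotone(ps):
    p = np.array(ps)
    adj = benjamini_hochberg(p)
    assert np.all(adj.adjusted >= adj.raw - 1e-12)
    assert np.all(adj.adjusted <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj.adjusted[order]) >= -1e-12)


def test_bh_controls_fdr_on_null_simulation():
    # 200 all-null features: mean false discovery proportion <= alpha + 3 SE
    rng = np.random.default_rng(5)
    alpha, reps = 0.05, 500
    fdp = np.empty(reps)
    for i in range(reps):
        q = benjamini_hochberg(rng.uniform(size=200)).adjusted
        r = int((q < alpha).sum())
        fdp[i] = 1.0 if r > 0 else 0.0  # all rejections are false here
    se = fdp.std(ddof=1) / np.sqrt(reps)
    assert fdp.mean() <= alpha + 3 * se


# ---------------------------------------------------------------------------
# NB Wald


def test_nb_wald_identical_groups_is_null():
    res, l2 = nb_wald_two_group(np.array([10, 12, 11]), np.array([10, 12, 11]))
    assert abs(l2) < 1e-9
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_nb_wald_all_zero_rule():
    res, l2 = nb_wald_two_group(np.zeros(3), np.zeros(3))
    assert l2 == 0.0 and res.p_value == 1.0


def test_nb_wald_large_count_effect_matches_normal_approx_oracle():
    a = np.array([100, 110, 90, 105], float)
    b = np.array([400, 380, 420, 410], float)
    res, l2 = nb_wald_two_group(a, b)
    assert l2 == pytest.approx(2.0, abs=0.1)
    assert res.p_value < 1e-3


def test_nb_wald_respects_size_factors():
    # doubling group-b size factors halves the scaled counts: no effect left
    a = np.array([50, 60, 55, 52], float)
    b = 2 * a
    sf = np.concatenate([np.ones(4), 2 * np.ones(4)])
    _, l2 = nb_wald_two_group(a, b, sf)
    assert abs(l2) < 1e-9


def test_nb_wald_rejects_tiny_groups():
    with pytest.raises(ValueError):
        nb_wald_two_group(np.array([1.0]), np.array([2.0, 3.0]))


def test_nb_wald_null_rejection_rate_calibrated():
    # equal NB means, dispersion 0.1, n=18/18: alpha=0.05 level in [0.03, 0.08]
    rng = np.random.default_rng(6)
    n_feat, n = 2000, 18
    mu = rng.uniform(20, 200, n_feat)[:, None]
    lam_a = rng.gamma(10.0, mu * 0.1, size=(n_feat, n))
    lam_b = rng.gamma(10.0, mu * 0.1, size=(n_feat, n))
    _, _, p = nb_wald_matrix(rng.poisson(lam_a), rng.poisson(lam_b))
    rate = (p < 0.05).mean()
    assert 0.03 <= rate <= 0.08


def test_nb_wald_concordant_with_pydeseq2_on_small_fixture():
    """Independent cross-check: effect sizes and significance calls agree
    with DESeq2's Wald test on a small planted-fold-change fixture (the
    two dispersion estimators differ, so agreement is approximate)."""
    import pandas as pd
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(0)
    n = 12
    mu = np.array([50.0, 80.0, 120.0, 200.0, 40.0])
    fc = np.array([1.0, 4.0, 1.0, 0.25, 1.0])
    counts = np.empty((2 * n, 5), dtype=int)
    for j in range(5):
        counts[:n, j] = rng.poisson(rng.gamma(10, mu[j] * 0.1, n))
        counts[n:, j] = rng.poisson(rng.gamma(10, mu[j] * fc[j] * 0.1, n))
    meta = pd.DataFrame({"condition": ["a"] * n + ["b"] * n},
                        index=[f"s{i}" for i in range(2 * n)])
    dds = DeseqDataSet(
        counts=pd.DataFrame(counts, index=meta.index, columns=[f"g{j}" for j in range(5)]),
        metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    st = DeseqStats(dds, contrast=["condition", "b", "a"], quiet=True)
    st.summary()
    ref = st.results_df

    l2, _, p = nb_wald_matrix(counts[:n].T, counts[n:].T)
    np.testing.assert_allclose(l2, ref["log2FoldChange"], atol=0.5)
    assert np.array_equal(p < 0.01, (ref["pvalue"] < 0.01).to_numpy())


def test_median_of_ratios_recovers_depth_scaling():
    rng = np.random.default_rng(7)
    base = rng.uniform(10, 100, size=(300, 1))
    factors = np.array([0.5, 1.0, 2.0, 4.0])
    counts = base * factors
    sf = median_of_ratios_size_factors(counts)
    np.testing.assert_allclose(sf / sf[1], factors, rtol=1e-9)
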