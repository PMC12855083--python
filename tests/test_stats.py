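"""Statistics battery against independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from fibrocyto.stats import (
    StatsInputError,
    bh_adjust,
    bky_two_stage,
    fisher_exact,
    kruskal_wallis,
    mann_whitney,
    pairwise_posthoc,
    spearman_screen,
    wilcoxon_paired,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _mw_exact_oracle(a, b):
    """Brute-force two-sided p: enumerate every split of the pooled ranks."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = sps.rankdata(pooled)

    def u_stat(idx_a):
        ra = ranks[list(idx_a)].sum()
        return ra - len(idx_a) * (len(idx_a) + 1) / 2

    u_obs = u_stat(range(len(a)))
    mean_u = len(a) * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), len(a)):
        total += 1
        if abs(u_stat(combo) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def test_mann_whitney_exact_worked_example():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.method == "mann-whitney-exact"
    assert r.p == pytest.approx(0.100, abs=1e-9)
    assert r.p == pytest.approx(_mw_exact_oracle([1, 2, 3], [4, 5, 6]))


def test_mann_whitney_exact_matches_enumeration_on_random_data(rng):
    for _ in range(5):
        a, b = rng.normal(size=4), rng.normal(size=5)
        r = mann_whitney(a, b)
        assert r.p == pytest.approx(_mw_exact_oracle(a, b), abs=1e-12)


def test_mann_whitney_symmetry_and_separation():
    assert mann_whitney([1, 2, 3], [1, 2, 3]).p == pytest.approx(1.0)
    a = np.arange(50.0)
    assert mann_whitney(a, a + 1000).p < 1e-6
    with pytest.raises(StatsInputError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kruskal_identical_groups():
    r = kruskal_wallis([[1, 2], [1, 2], [2, 1]])
    assert r.statistic == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)


def test_kruskal_exact_matches_bruteforce():
    """Total n=6: enumerate all 6!/(2!2!2!)=90 partitions with scipy's H."""
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    r = kruskal_wallis(groups)
    assert r.method == "kruskal-wallis-exact"
    pooled = np.array([1.0, 2, 3, 4, 5, 6])
    h_obs = sps.kruskal(*groups).statistic
    assert r.statistic == pytest.approx(h_obs)
    count = total = 0
    for combo_a in itertools.combinations(range(6), 2):
        rest = [i for i in range(6) if i not in combo_a]
        for combo_b in itertools.combinations(rest, 2):
            combo_c = [i for i in rest if i not in combo_b]
            total += 1
            h = sps.kruskal(pooled[list(combo_a)], pooled[list(combo_b)],
                            pooled[combo_c]).statistic
            if h >= h_obs - 1e-12:
                count += 1
    assert r.p == pytest.approx(count / total)


def test_two_group_kruskal_equals_squared_mw_z_asymptotically(rng):
    a, b = rng.normal(0, 1, 100), rng.normal(0.3, 1, 100)
    kw = kruskal_wallis([a, b])
    # H ~ z^2: chi2(1) upper tail of H equals the two-sided normal p of z
    z = sps.norm.isf(mann_whitney(a, b).p / 2)
    assert kw.statistic == pytest.approx(z**2, rel=0.05)
    with pytest.raises(StatsInputError):
        kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Wilcoxon / Fisher
# ---------------------------------------------------------------------------


def test_wilcoxon_all_zero_differences():
    with pytest.warns(UserWarning):
        r = wilcoxon_paired([1, 2, 3], [1, 2, 3])
    assert r.p == 1.0 and r.notes["n_used"] == 0


def test_wilcoxon_exact_sign_enumeration():
    """Differences +1..+5: only 2 of the 2^5 sign assignments are as extreme."""
    r = wilcoxon_paired([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
    assert r.method == "wilcoxon-exact"
    assert r.p == pytest.approx(2 / 32)


def test_wilcoxon_antisymmetric_differences():
    r = wilcoxon_paired([0, 0, 0, 0], [-2, -1, 1, 2])
    assert r.p == pytest.approx(1.0)
    with pytest.raises(StatsInputError):
        wilcoxon_paired([1, 2], [1, 2, 3])


def test_fisher_exact_worked_examples():
    assert fisher_exact([[2, 0], [0, 2]]).p == pytest.approx(1 / 3)
    assert fisher_exact([[5, 5], [5, 5]]).p == pytest.approx(1.0)
    t = [[7, 2], [3, 9]]
    assert fisher_exact(t).p == pytest.approx(fisher_exact(t[::-1]).p)
    with pytest.raises(StatsInputError):
        fisher_exact([[1, -1], [0, 2]])


# ---------------------------------------------------------------------------
# BH / BKY
# ---------------------------------------------------------------------------


def test_bh_hand_worked_example():
    adj = bh_adjust([0.01, 0.02, 0.03])
    assert adj == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_dominates_raw_p(pvals):
    adj = bh_adjust(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()


def _bky_literal(p, alpha):
    """Independent literal two-stage implementation (stage-1 BH at
    alpha/(1+alpha); stage-2 BH at that level scaled by m/m0)."""
    p = np.asarray(p, float)
    m = len(p)
    q = alpha / (1 + alpha)

    def bh(level):
        order = np.argsort(p)
        ps = p[order]
        passed = ps <= level * np.arange(1, m + 1) / m
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        rej = np.zeros(m, bool)
        rej[order[:k]] = True
        return rej

    r1 = bh(q).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return bh(q * m / (m - r1))


def test_bky_worked_example_and_oracles():
    p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.07, 0.08, 0.09, 0.1]
    rejected, adjusted = bky_two_stage(p, alpha=0.05)
    assert np.array_equal(rejected, _bky_literal(p, 0.05))
    # statsmodels implements the same two-stage definition
    sm_rej = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
    assert np.array_equal(rejected, sm_rej)
    assert (adjusted >= 0).all() and (adjusted <= 1).all()


def test_bky_edge_cases():
    rej, _ = bky_two_stage([1.0, 1.0, 1.0])
    assert not rej.any()
    rej, _ = bky_two_stage([0.01], alpha=0.05)
    assert rej.all()
    with pytest.raises(StatsInputError):
        bky_two_stage([0.5, 1.5])


def test_bky_rejections_contain_bh_rejections(rng):
    """On mixtures with genuine effects the adaptive pass is never less
    powerful than plain BH at the same level."""
    for _ in range(50):
        p = np.concatenate([
            rng.uniform(0, 1e-4, 30),  # strong true effects
            rng.uniform(0, 1, 170),
        ])
        bky_rej, _ = bky_two_stage(p, alpha=0.05)
        bh_rej = bh_adjust(p) <= 0.05
        assert (bky_rej | ~bh_rej).all()


def test_pairwise_posthoc_family(rng):
    groups = {"HC": rng.normal(0, 1, 9), "RA": rng.normal(2, 1, 11),
              "PsA": rng.normal(2, 1, 12)}
    results = pairwise_posthoc(groups)
    assert len(results) == 3
    by_cmp = {r.notes["comparison"]: r for r in results}
    assert by_cmp["HC vs RA"].rejected and by_cmp["HC vs PsA"].rejected


# ---------------------------------------------------------------------------
# type-I error calibration
# ---------------------------------------------------------------------------


def test_type_one_error_under_global_null(rng):
    """MW and KW reject at most alpha + Monte-Carlo tolerance under the null."""
    alpha, n_sim = 0.05, 5000
    mw = kw = 0
    for _ in range(n_sim):
        x = rng.normal(size=(3, 10))
        if mann_whitney(x[0], x[1]).p < alpha:
            mw += 1
        if sps.kruskal(*x).pvalue < alpha:  # asymptotic path, same statistic
            kw += 1
    tol = 3 * np.sqrt(alpha * (1 - alpha) / n_sim)
    assert mw / n_sim <= alpha + tol
    assert kw / n_sim <= alpha + tol


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------


def test_spearman_monotone_anchors():
    import pandas as pd

    x = pd.DataFrame([np.arange(10.0)], index=["x"])
    y = pd.DataFrame([np.exp(np.arange(10.0)), -np.arange(10.0)], index=["up", "down"])
    res = {r.y_name: r for r in spearman_screen(x, y)}
    assert res["up"].rho == pytest.approx(1.0)
    assert res["down"].rho == pytest.approx(-1.0)


def test_spearman_mean_matches_closed_form(rng):
    """Bivariate normal, rho=0.5, n=23: mean sample Spearman matches the
    finite-n expectation 6/(pi(n+1)) [asin(rho) + (n-2) asin(rho/2)]."""
    rho, n, reps = 0.5, 23, 2000
    cov = [[1, rho], [rho, 1]]
    vals = np.empty(reps)
    for i in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        vals[i] = sps.spearmanr(xy[:, 0], xy[:, 1]).statistic
    expected = 6 / (np.pi * (n + 1)) * (np.arcsin(rho) + (n - 2) * np.arcsin(rho / 2))
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean() - expected) < 3 * se


def test_spearman_short_pairs_skipped():
    import pandas as pd

    x = pd.DataFrame([[1.0, 2.0]], index=["x"], columns=["a", "b"])
    y = pd.DataFrame([[1.0, 2.0]], index=["y"], columns=["a", "b"])
    with pytest.warns(UserWarning):
        assert spearman_screen(x, y) == []
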