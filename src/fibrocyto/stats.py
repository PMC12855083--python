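"""Nonparametric cohort statistics and FDR control.

The battery used for count comparisons: Mann-Whitney U (exact for small
untied samples), Kruskal-Wallis with an exact small-sample path, the paired
Wilcoxon signed-rank test, Fisher's exact test, Benjamini-Hochberg step-up
adjustment, the two-stage adaptive step-up procedure of Benjamini, Krieger &
Yekutieli (BKY), and Spearman/Pearson correlation screens with BH control.

Conventions that change answers and are therefore fixed here:

* two-sided Fisher p is the sum of hypergeometric probabilities no larger
  than that of the observed table (the convention of common software);
* Wilcoxon drops zero differences (signed-rank convention), which reduces n;
* the BKY second-stage BH pass runs at level alpha' * m / m0 with
  alpha' = alpha / (1 + alpha), i.e. the literal two-stage definition. The
  procedure reduces to plain BH at alpha' when the first stage rejects
  nothing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsInputError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    adjusted_p: float | None = None
    rejected: bool | None = None
    notes: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p: float
    n: int
    adjusted_p: float | None = None
    method: str = "spearman"


def _as1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise StatsInputError(f"{name}: empty group")
    return a


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact p by enumeration of rank assignments when nA+nB <= 12 and the
    pooled data are tie-free; normal approximation with tie correction (and
    continuity correction) otherwise.
    """
    a, b = _as1d(group_a, "group_a"), _as1d(group_b, "group_b")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) + len(b) <= 12) and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method="mann-whitney-exact" if exact else "mann-whitney-normal",
        n=(len(a), len(b)),
    )


def _kw_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis across >= 2 groups.

    Chi-square p on k-1 df; for total n <= 10 the p-value is computed
    exactly by enumerating every assignment of the pooled observations to
    the group sizes.
    """
    gs = [_as1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise StatsInputError("kruskal_wallis needs at least two groups")
    sizes = [len(g) for g in gs]
    n = sum(sizes)
    h_obs = _kw_h(gs)
    if n <= 10:
        pooled = np.concatenate(gs)
        count = total = 0
        for perm in _distinct_partitions(pooled, sizes):
            total += 1
            if _kw_h(perm) >= h_obs - 1e-12:
                count += 1
        p = count / total
        method = "kruskal-wallis-exact"
    else:
        p = float(sps.chi2.sf(h_obs, df=len(gs) - 1))
        method = "kruskal-wallis-chi2"
    return TestResult(statistic=h_obs, p=p, method=method, n=tuple(sizes))


def _distinct_partitions(pooled: np.ndarray, sizes: list[int]):
    """All distinct assignments of pooled values into ordered groups of given sizes.

    Enumerates index combinations recursively (multinomial(n; sizes) cases)
    and deduplicates assignments that tie-equal values make indistinguishable.
    """
    n = len(pooled)
    seen = set()

    def rec(remaining: tuple[int, ...], acc: list[np.ndarray]):
        if len(acc) == len(sizes):
            key = tuple(tuple(np.sort(g)) for g in acc)
            if key not in seen:
                seen.add(key)
                yield [g.copy() for g in acc]
            return
        k = sizes[len(acc)]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, acc + [pooled[list(combo)]])

    yield from rec(tuple(range(n)), [])


def wilcoxon_paired(before, after) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test; zero differences dropped."""
    b, a = np.asarray(before, dtype=float), np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise StatsInputError(f"length mismatch: {b.shape} vs {a.shape}")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; returning p=1 with n_used=0")
        return TestResult(statistic=0.0, p=1.0, method="wilcoxon-degenerate",
                          n=(len(d),), notes={"n_used": 0})
    exact = len(nz) <= 15 and len(np.unique(np.abs(nz))) == len(nz)
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                       method="exact" if exact else "approx", correction=not exact)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        method="wilcoxon-exact" if exact else "wilcoxon-normal",
        n=(len(d),), notes={"n_used": len(nz)},
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsInputError("fisher_exact needs a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t != np.floor(t)).any() or (t < 0).any():
            raise StatsInputError("fisher_exact needs nonnegative integer counts")
        t = t.astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), method="fisher-exact",
                      n=tuple(int(x) for x in t.sum(axis=1)))


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if len(p) == 0:
        raise StatsInputError("empty p-value vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise StatsInputError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = _check_pvalues(pvalues)
    return multipletests(p, method="fdr_bh")[1]


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    """Plain BH step-up rejection set at the given level."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = level * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected


def bky_two_stage(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive step-up FDR control (Benjamini-Krieger-Yekutieli).

    Stage 1 runs BH at alpha' = alpha/(1+alpha); r1 rejections estimate the
    number of true nulls m0 = m - r1. If r1 = 0 nothing is rejected; if
    r1 = m everything is. Otherwise stage 2 re-runs BH at alpha' * m / m0.

    Returns ``(rejected, adjusted_p)`` where the adaptive adjusted p-values
    are the BH values scaled by the estimated null fraction m0/m.
    """
    p = _check_pvalues(pvalues)
    if not 0 < alpha < 1:
        raise StatsInputError("alpha must be in (0, 1)")
    m = len(p)
    alpha_prime = alpha / (1 + alpha)
    stage1 = _bh_reject(p, alpha_prime)
    r1 = int(stage1.sum())
    bh_p = bh_adjust(p)
    if r1 == 0:
        return stage1, bh_p
    if r1 == m:
        return np.ones(m, dtype=bool), np.minimum(bh_p * 0.0, 1.0)
    m0 = m - r1
    rejected = _bh_reject(p, alpha_prime * m / m0)
    adjusted = np.minimum(bh_p * m0 / m, 1.0)
    return rejected, adjusted


def pairwise_posthoc(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[TestResult]:
    """All pairwise Mann-Whitney comparisons corrected as one BKY family."""
    names = list(groups)
    results = []
    for a, b in itertools.combinations(names, 2):
        r = mann_whitney(groups[a], groups[b])
        r.notes["comparison"] = f"{a} vs {b}"
        results.append(r)
    rejected, adjusted = bky_two_stage([r.p for r in results], alpha)
    for r, rej, adj in zip(results, rejected, adjusted):
        r.rejected, r.adjusted_p = bool(rej), float(adj)
    return results


def spearman_screen(x_table, y_table) -> list[CorrelationResult]:
    """Spearman rho for every (row of x) x (row of y) pair, BH-adjusted.

    Tables are DataFrames (quantities x samples) with matched columns. Pairs
    with n < 3 usable samples, or a constant vector, are skipped with a
    warning.
    """
    results: list[CorrelationResult] = []
    common = [c for c in x_table.columns if c in set(y_table.columns)]
    for xn, xrow in x_table.iterrows():
        for yn, yrow in y_table.iterrows():
            x = xrow[common].to_numpy(dtype=float)
            y = yrow[common].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(f"pair ({xn}, {yn}): fewer than 3 samples; skipped")
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                warnings.warn(f"pair ({xn}, {yn}): constant vector; skipped")
                continue
            rho, p = sps.spearmanr(x[ok], y[ok])
            results.append(CorrelationResult(str(xn), str(yn), float(rho), float(p),
                                             int(ok.sum())))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results
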