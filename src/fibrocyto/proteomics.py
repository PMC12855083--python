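"""Plasma-proteomics arm: NPX QC, moderated differential expression,
preranked gene-set enrichment, and protein-vs-cell-count correlations.

NPX (Normalized Protein eXpression) values are relative abundances on a
log2 scale, so a two-group difference of means *is* the log2 fold change.

Differential expression uses an empirical-Bayes moderated t: per-assay
residual variances s^2 with d degrees of freedom are shrunk toward a prior
(d0, s0^2) estimated by moment-matching the log-variances. Under the
hierarchical model s^2/s0^2 ~ F(d, d0)-scaled, so

    Var[log s^2]  = trigamma(d/2) + trigamma(d0/2)
    E[log s^2]    = log s0^2 + digamma(d/2) - log(d/2)
                            - digamma(d0/2) + log(d0/2)

which gives d0 by trigamma inversion and s0^2 in closed form. The posterior
variance is s~^2 = (d0 s0^2 + d s^2)/(d0 + d) and the moderated t has
d + d0 degrees of freedom. Setting d0 = 0 recovers the ordinary t; d0 = inf
pools every assay to the common s0.

Preranked enrichment uses the weighted Kolmogorov-Smirnov running sum with
weight w = 1 (hit increments proportional to |statistic|), a gene-label
permutation null, and sign-matched NES normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .stats import bh_adjust


class ProteomicsError(ValueError):
    pass


@dataclass
class NPXMatrix:
    """Assays x samples NPX values with per-assay QC and sample metadata."""

    values: pd.DataFrame  # index assay, columns sample_id
    assay_qc: pd.DataFrame  # columns: warning (bool), below_lod_frac, lod
    sample_meta: pd.DataFrame  # index sample_id: group, detectable_cdh11_fib

    @property
    def n_assays(self) -> int:
        return len(self.values)

    def to_long_csv(self, path) -> None:
        """Olink-style long format: SampleID, Assay, NPX, QC_Warning, LOD."""
        long = self.values.stack().rename("NPX").reset_index()
        long.columns = ["Assay", "SampleID", "NPX"]
        long["QC_Warning"] = long["Assay"].map(
            self.assay_qc["warning"].map({True: "Warning", False: "Pass"})
        )
        long["LOD"] = long["Assay"].map(self.assay_qc["lod"])
        long[["SampleID", "Assay", "NPX", "QC_Warning", "LOD"]].to_csv(path, index=False)

    @staticmethod
    def from_long_csv(path, sample_meta: pd.DataFrame | None = None) -> "NPXMatrix":
        long = pd.read_csv(path)
        values = long.pivot(index="Assay", columns="SampleID", values="NPX")
        values.index.name = "assay"
        warning = long.groupby("Assay")["QC_Warning"].first() != "Pass"
        lod = long.groupby("Assay")["LOD"].first()
        below = (values.lt(lod, axis=0)).mean(axis=1)
        qc = pd.DataFrame({"warning": warning, "below_lod_frac": below, "lod": lod})
        if sample_meta is None:
            sample_meta = pd.DataFrame(index=values.columns)
        return NPXMatrix(values=values, assay_qc=qc.loc[values.index], sample_meta=sample_meta)


def qc_filter(matrix: NPXMatrix, max_below_lod: float = 0.5) -> NPXMatrix:
    """Drop assays with a QC warning or too many below-LOD samples."""
    qc = matrix.assay_qc
    keep = (~qc["warning"]) & (qc["below_lod_frac"] <= max_below_lod)
    if not keep.any():
        raise ProteomicsError("QC removed every assay; nothing left to analyze")
    dropped = list(qc.index[~keep])
    if dropped:
        warnings.warn(f"QC removed {len(dropped)} assays: {dropped[:8]}{'...' if len(dropped) > 8 else ''}")
    return NPXMatrix(
        values=matrix.values.loc[keep[keep].index],
        assay_qc=qc.loc[keep[keep].index],
        sample_meta=matrix.sample_meta,
    )


# ---------------------------------------------------------------------------
# moderated differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame  # per-assay: log2fc, t_ordinary, t_moderated, p, p_adj, dep
    d: float  # residual df per assay
    d0: float  # prior df
    s0_sq: float  # prior variance


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a convex decreasing map)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-assay sample variances."""
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s_sq)) if len(s_sq) else 1.0
    z = np.log(s_sq[ok])
    evar = np.var(z, ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        d0 = math.inf
        log_s0 = float(np.mean(z)) - special.digamma(d / 2) + math.log(d / 2)
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        log_s0 = (
            float(np.mean(z))
            - special.digamma(d / 2)
            + math.log(d / 2)
            + special.digamma(d0 / 2)
            - math.log(d0 / 2)
        )
    return d0, float(np.exp(log_s0))


def differential_expression(
    matrix: NPXMatrix,
    contrast,
    prior_df: float | None = None,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> DEResult:
    """Per-assay moderated two-group comparison.

    ``contrast`` is a Boolean/0-1 indicator over the matrix's samples (True =
    test group). log2FC is the group-mean difference on the NPX scale.
    ``prior_df`` overrides the estimated d0 (0 disables shrinkage, ``inf``
    pools fully).
    """
    g = np.asarray(contrast, dtype=bool)
    if g.shape[0] != matrix.values.shape[1]:
        raise ProteomicsError("contrast length does not match the number of samples")
    n1, n2 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n2 < 2:
        raise ProteomicsError(f"each group needs >= 2 samples, got {n1} and {n2}")

    x = matrix.values.to_numpy(dtype=float)
    a, b = x[:, g], x[:, ~g]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    d = float(n1 + n2 - 2)
    pooled = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / d
    se_factor = math.sqrt(1.0 / n1 + 1.0 / n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = lfc / (np.sqrt(pooled) * se_factor)

    d0, s0_sq = estimate_prior(pooled, d) if prior_df is None else (prior_df, None)
    if prior_df is not None and s0_sq is None:
        s0_sq = estimate_prior(pooled, d)[1]
    if math.isinf(d0):
        s_tilde = np.full_like(pooled, s0_sq)
        df_total = math.inf
    else:
        s_tilde = (d0 * s0_sq + d * pooled) / (d0 + d)
        df_total = d + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / (np.sqrt(s_tilde) * se_factor)
    if math.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2 * sps.t.sf(np.abs(t_mod), df=df_total)
    p_adj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p": p,
            "p_adj": p_adj,
            "dep": (p_adj < p_threshold) & (np.abs(lfc) > lfc_threshold),
        },
        index=matrix.values.index,
    )
    return DEResult(table=table, d=d, d0=d0, s0_sq=float(s0_sq))


def select_deps(result: DEResult, p_threshold: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Differentially expressed proteins: adjusted p below and |log2FC| above threshold."""
    t = result.table
    return t[(t["p_adj"] < p_threshold) & (t["log2fc"].abs() > lfc_threshold)]


# ---------------------------------------------------------------------------
# preranked gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    adjusted_p: float | None
    size: int
    leading_edge: list[str] = field(default_factory=list)


def _es_and_edge(order: np.ndarray, stat_sorted: np.ndarray, hit_mask: np.ndarray,
                 weight: float) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score on a pre-sorted ranking."""
    n = len(stat_sorted)
    w = np.abs(stat_sorted) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total_hit = hit_w.sum()
    n_hit = int(hit_mask.sum())
    if total_hit == 0 or n_hit == n:
        return 0.0, np.zeros(0, dtype=int)
    miss = 1.0 / (n - n_hit)
    running = np.cumsum(np.where(hit_mask, hit_w / total_hit, -miss))
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        edge = np.flatnonzero(hit_mask[: i_max + 1])
    else:
        edge = np.flatnonzero(hit_mask[i_max:]) + i_max
    return es, edge


def preranked_gsea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 3,
    exhaustive: bool = False,
) -> list[EnrichmentResult]:
    """Preranked enrichment over a collection of gene sets.

    ES is the maximum deviation of the weighted running sum; the null is
    gene-label permutation (``n_perm`` random same-size sets, or every
    possible set when ``exhaustive``); NES normalizes ES by the mean |null|
    of the matching sign; p = (1 + #{|null| >= |ES|, same sign})/(n_null + 1).
    """
    if ranking.isna().any():
        raise ProteomicsError("ranking contains NaN statistics")
    ranking = ranking.sort_values(ascending=False)
    genes = np.array(ranking.index)
    stat = ranking.to_numpy(dtype=float)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    results = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        hits = [pos[g] for g in members if g in pos]
        if len(hits) < min_size:
            warnings.warn(f"set {name!r}: only {len(hits)} of {len(members)} members in the "
                          f"ranking (min {min_size}); skipped")
            continue
        k = len(hits)
        mask = np.zeros(n, dtype=bool)
        mask[hits] = True
        es, edge = _es_and_edge(None, stat, mask, weight)

        if k not in null_cache:
            if exhaustive:
                from itertools import combinations

                null = []
                for combo in combinations(range(n), k):
                    m = np.zeros(n, dtype=bool)
                    m[list(combo)] = True
                    null.append(_es_and_edge(None, stat, m, weight)[0])
                null = np.array(null)
            else:
                null = np.empty(n_perm)
                for i in range(n_perm):
                    m = np.zeros(n, dtype=bool)
                    m[rng.choice(n, size=k, replace=False)] = True
                    null[i] = _es_and_edge(None, stat, m, weight)[0]
            null_cache[k] = null
        null = null_cache[k]

        same_sign = null >= 0 if es >= 0 else null < 0
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else float("nan")
        extreme = int((same_sign & (np.abs(null) >= abs(es))).sum())
        p = (1 + extreme) / (len(null) + 1)
        results.append(
            EnrichmentResult(
                set_name=name, es=es, nes=float(nes), p=float(p), adjusted_p=None,
                size=k, leading_edge=[str(genes[i]) for i in edge],
            )
        )
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# protein vs cell-count correlation screen
# ---------------------------------------------------------------------------


def protein_cell_correlation(
    matrix: NPXMatrix,
    cell_counts: pd.DataFrame,
    protein_subset=None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Pearson correlations between NPX levels and cell-population counts.

    ``cell_counts`` is quantities x samples with columns matching the NPX
    samples. ``protein_subset`` restricts the screen (typically to proteins
    in significantly enriched sets). BH-adjusted significance at ``alpha``.
    """
    proteins = list(protein_subset) if protein_subset is not None else list(matrix.values.index)
    proteins = [p for p in proteins if p in matrix.values.index]
    common = [c for c in matrix.values.columns if c in set(cell_counts.columns)]
    rows = []
    for prot in proteins:
        x = matrix.values.loc[prot, common].to_numpy(dtype=float)
        for qty, crow in cell_counts.iterrows():
            y = crow[common].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(f"pair ({prot}, {qty}): fewer than 3 samples; skipped")
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                warnings.warn(f"pair ({prot}, {qty}): constant vector; skipped")
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append({"protein": prot, "quantity": qty, "r": float(r),
                         "p": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["protein", "quantity", "r", "p", "n"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out
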