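"""NPX QC, moderated differential expression, preranked enrichment and
correlation screens, with R limma and exhaustive enumeration as oracles."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibrocyto.design import build_default_design
from fibrocyto.proteomics import (
    NPXMatrix,
    ProteomicsError,
    differential_expression,
    preranked_gsea,
    protein_cell_correlation,
    qc_filter,
    select_deps,
)


def _matrix(values: np.ndarray, warnings=None, groups=None) -> NPXMatrix:
    m, n = values.shape
    idx = pd.Index([f"A{i:03d}" for i in range(m)], name="assay")
    cols = [f"S{j:02d}" for j in range(n)]
    qc = pd.DataFrame({
        "warning": warnings if warnings is not None else np.zeros(m, bool),
        "below_lod_frac": 0.0,
        "lod": -10.0,
    }, index=idx)
    meta = pd.DataFrame({"group": groups if groups is not None else ["g"] * n},
                        index=pd.Index(cols, name="sample_id"))
    return NPXMatrix(values=pd.DataFrame(values, index=idx, columns=cols),
                     assay_qc=qc, sample_meta=meta)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def test_qc_removes_flagged_assays(rng):
    w = np.zeros(368, bool)
    w[:10] = True
    m = _matrix(rng.normal(size=(368, 8)), warnings=w)
    with pytest.warns(UserWarning):
        out = qc_filter(m)
    assert out.n_assays == 358


def test_qc_identity_without_flags(rng):
    m = _matrix(rng.normal(size=(20, 6)))
    out = qc_filter(m)
    assert out.n_assays == 20
    pd.testing.assert_frame_equal(out.values, m.values)


def test_qc_all_flagged_is_an_error(rng):
    m = _matrix(rng.normal(size=(5, 6)), warnings=np.ones(5, bool))
    with pytest.raises(ProteomicsError):
        qc_filter(m)


def test_npx_long_csv_round_trip(tmp_path, rng):
    w = np.zeros(12, bool)
    w[3] = True
    m = _matrix(rng.normal(size=(12, 5)), warnings=w)
    path = tmp_path / "npx.csv"
    m.to_long_csv(path)
    back = NPXMatrix.from_long_csv(path)
    pd.testing.assert_frame_equal(
        back.values.sort_index(), m.values.sort_index(), check_names=False
    )
    assert back.assay_qc.loc["A003", "warning"]


# ---------------------------------------------------------------------------
# moderated differential expression
# ---------------------------------------------------------------------------


def test_prior_df_limits(rng):
    x = rng.normal(0, rng.uniform(0.5, 2, (60, 1)), size=(60, 12))
    m = _matrix(x)
    g = np.array([True] * 6 + [False] * 6)
    off = differential_expression(m, g, prior_df=0.0)
    np.testing.assert_allclose(off.table.t_moderated, off.table.t_ordinary)
    full = differential_expression(m, g, prior_df=np.inf)
    # full pooling: one common variance for every assay
    se = full.table.log2fc / full.table.t_moderated
    assert np.allclose(se, se.iloc[0])


def test_moderated_t_matches_limma(tmp_path, rng):
    """Same shrinkage machinery as the reference empirical-Bayes fit."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    n1 = n2 = 5
    x = rng.normal(0, rng.uniform(0.5, 2, (50, 1)), size=(50, n1 + n2))
    x[:5, :n1] += 2
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
    csv, out = tmp_path / "x.csv", tmp_path / "out.csv"
    df.to_csv(csv)
    script = f"""
    x <- as.matrix(read.csv("{csv}", row.names=1))
    suppressMessages(library(limma))
    design <- cbind(Intercept=1, grp=c(rep(1,{n1}), rep(0,{n2})))
    fit <- eBayes(lmFit(x, design))
    write.csv(data.frame(t=fit$t[,"grp"], p=fit$p.value[,"grp"],
                         d0=fit$df.prior, s0=fit$s2.prior), "{out}")
    """
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"limma not runnable: {proc.stderr[-200:]}")
    ref = pd.read_csv(out, index_col=0)
    de = differential_expression(_matrix(x), np.array([True] * n1 + [False] * n2))
    assert de.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert de.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
    np.testing.assert_allclose(de.table.t_moderated, ref["t"], rtol=1e-8)
    np.testing.assert_allclose(de.table.p, ref["p"], rtol=1e-8)


def test_null_moderated_p_values_are_uniform(rng):
    """Heteroscedastic null (variances from the scaled-inv-chi2 prior):
    raw moderated p-values are uniform."""
    m_assays, n1, n2 = 2000, 10, 10
    d0_true, s0 = 4.0, 0.5
    variances = d0_true * s0 / rng.chisquare(d0_true, m_assays)
    x = rng.normal(0, np.sqrt(variances)[:, None], size=(m_assays, n1 + n2))
    de = differential_expression(_matrix(x), np.array([True] * n1 + [False] * n2))
    frac = (de.table.p < 0.05).mean()
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m_assays)
    assert sps.kstest(de.table.p, "uniform").pvalue > 0.005


def test_dep_selection_gates(rng):
    x = rng.normal(size=(10, 8)) * 0.1
    x[0, :4] += 3.0  # large shift, small variance
    x[1, :4] += 0.5  # significant but small fold change
    de = differential_expression(_matrix(x), np.array([True] * 4 + [False] * 4))
    deps = select_deps(de)
    t = de.table
    assert ((deps.p_adj < 0.05) & (deps.log2fc.abs() > 1)).all()
    small_fc = t[(t.p_adj < 0.05) & (t.log2fc.abs() <= 1)]
    assert not small_fc.index.isin(deps.index).any()


def test_effect_proteins_recovered_across_replicate_cohorts():
    """+2 log2 on the three designated proteins, 13 detectable vs 7 not:
    they are the top three by adjusted p and pass both DEP gates in >= 90%
    of replicate cohorts."""
    from conftest import patient_truth
    from fibrocyto.simulate import simulate_npx

    design = build_default_design()
    truth = patient_truth(13, 7)
    effect = set(design.npx_effects)
    wins = 0
    reps = 40
    for r in range(reps):
        npx = simulate_npx(design, truth, seed=1000 + r)
        with pytest.warns(UserWarning):
            filt = qc_filter(npx)
        de = differential_expression(filt, filt.sample_meta.detectable_cdh11_fib.to_numpy())
        retained = effect & set(filt.values.index)
        top = set(de.table.sort_values("p_adj").head(len(retained)).index)
        deps = set(select_deps(de).index)
        if top == retained and retained <= deps:
            wins += 1
    assert wins / reps >= 0.9


def test_de_requires_two_per_group(rng):
    m = _matrix(rng.normal(size=(5, 4)))
    with pytest.raises(ProteomicsError):
        differential_expression(m, np.array([True, False, False, False]))


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _ranking():
    return pd.Series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.3, 0.1],
                     index=list("ABCDEFGH"))


def test_es_saturates_at_extremes():
    res = preranked_gsea(_ranking(), {"top": ["A", "B", "C"],
                                      "bottom": ["F", "G", "H"]}, exhaustive=True)
    by = {r.set_name: r for r in res}
    assert by["top"].es == pytest.approx(1.0)
    assert by["bottom"].es == pytest.approx(-1.0)
    assert np.sign(by["top"].nes) == 1 and np.sign(by["bottom"].nes) == -1


def _es_oracle(stat_sorted, hit_idx, weight=1.0):
    """Independent running-sum implementation for the enumeration oracle."""
    n = len(stat_sorted)
    hits = set(hit_idx)
    w = np.abs(stat_sorted) ** weight
    total = sum(w[i] for i in hits)
    miss = 1.0 / (n - len(hits))
    run = best = 0.0
    for i in range(n):
        run += w[i] / total if i in hits else -miss
        if abs(run) > abs(best):
            best = run
    return best


def test_permutation_p_matches_exhaustive_enumeration():
    """8-gene universe, 3-gene set: p over all C(8,3)=56 label choices."""
    ranking = _ranking()
    members = ["A", "C", "F"]
    res = preranked_gsea(ranking, {"s": members}, exhaustive=True)[0]
    stat = ranking.sort_values(ascending=False).to_numpy()
    genes = list(ranking.sort_values(ascending=False).index)
    es_obs = _es_oracle(stat, [genes.index(g) for g in members])
    assert res.es == pytest.approx(es_obs)
    nulls = [
        _es_oracle(stat, combo) for combo in itertools.combinations(range(8), 3)
    ]
    same = [e for e in nulls if (e >= 0) == (es_obs >= 0)]
    p_oracle = (1 + sum(abs(e) >= abs(es_obs) for e in same)) / (len(nulls) + 1)
    assert res.p == pytest.approx(p_oracle)


def test_gsea_seed_determinism(rng):
    ranking = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
    sets = {"a": [f"g{i}" for i in range(5)], "b": [f"g{i}" for i in range(20, 28)]}
    r1 = preranked_gsea(ranking, sets, n_perm=500, seed=7)
    r2 = preranked_gsea(ranking, sets, n_perm=500, seed=7)
    for x, y in zip(r1, r2):
        assert (x.es, x.nes, x.p) == (y.es, y.nes, y.p)


def test_es_rescaling_invariance_only_at_weight_zero():
    ranking = _ranking()
    cubed = ranking**3  # monotone rescale, same order
    sets = {"s": ["A", "C", "F"]}
    w0 = preranked_gsea(ranking, sets, exhaustive=True, weight=0.0)[0].es
    w0_scaled = preranked_gsea(cubed, sets, exhaustive=True, weight=0.0)[0].es
    assert w0 == pytest.approx(w0_scaled)
    w1 = preranked_gsea(ranking, sets, exhaustive=True, weight=1.0)[0].es
    w1_scaled = preranked_gsea(cubed, sets, exhaustive=True, weight=1.0)[0].es
    assert w1 != pytest.approx(w1_scaled, abs=1e-6)


def test_small_sets_skipped_with_warning():
    with pytest.warns(UserWarning):
        res = preranked_gsea(_ranking(), {"tiny": ["A", "Z"]}, n_perm=10)
    assert res == []


def test_nan_ranking_rejected():
    r = _ranking()
    r.iloc[0] = np.nan
    with pytest.raises(ProteomicsError):
        preranked_gsea(r, {"s": ["A", "B", "C"]})


# ---------------------------------------------------------------------------
# protein vs cell-count correlations
# ---------------------------------------------------------------------------


def test_linear_protein_count_relation(rng):
    counts = pd.DataFrame([np.arange(10.0)], index=["fibrocytes"],
                          columns=[f"S{j:02d}" for j in range(10)])
    values = np.vstack([2.0 * np.arange(10.0) + 1.0, rng.normal(size=10)])
    m = _matrix(values)
    res = protein_cell_correlation(m, counts)
    r0 = res.set_index("protein").loc["A000"]
    assert r0["r"] == pytest.approx(1.0)
    assert bool(r0["significant"])


def test_constant_protein_skipped(rng):
    counts = pd.DataFrame([np.arange(6.0)], index=["q"],
                          columns=[f"S{j:02d}" for j in range(6)])
    values = np.vstack([np.full(6, 3.0), rng.normal(size=6)])
    with pytest.warns(UserWarning):
        res = protein_cell_correlation(_matrix(values), counts)
    assert "A000" not in set(res["protein"])


def test_null_screen_controls_false_positives(rng):
    """Global null, BH at 0.1: the fraction of replicates with any rejection
    stays at or below the nominal level plus Monte-Carlo tolerance."""
    reps, hits = 60, 0
    for _ in range(reps):
        counts = pd.DataFrame(rng.normal(size=(10, 20)),
                              index=[f"q{i}" for i in range(10)],
                              columns=[f"S{j:02d}" for j in range(20)])
        m = _matrix(rng.normal(size=(10, 20)))
        res = protein_cell_correlation(m, counts, alpha=0.1)
        hits += int(res["significant"].any())
    assert hits / reps <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / reps)
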