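#!/usr/bin/env python
"""NPX proteomics arm on the simulated cohort.

Simulates the 368-assay NPX panel tied to the cohort's fibroblast ground
truth, applies QC, contrasts samples with vs without detectable CDH11+
fibroblasts with the moderated t, runs preranked enrichment over synthetic
gene sets (one chemokine-signaling-like set seeded with CXCL1, one
adhesion-like set with ANGPT1/TIMP3, plus random sets), and screens
proteins of significant sets against gated cell counts.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fibrocyto.design import build_default_design
from fibrocyto.proteomics import (
    differential_expression,
    preranked_gsea,
    protein_cell_correlation,
    qc_filter,
    select_deps,
)
from fibrocyto.simulate import SyntheticTruth, simulate_npx

ROOT = Path(__file__).resolve().parents[1]


def synthetic_gene_sets(assays, rng) -> dict[str, list[str]]:
    pool = [a for a in assays if a not in ("CXCL1", "ANGPT1", "TIMP3")]
    sets = {
        "CHEMOKINE_SIGNALING_LIKE": ["CXCL1"] + list(rng.choice(pool, 7, replace=False)),
        "CELL_SUBSTRATE_ADHESION_LIKE": ["ANGPT1", "TIMP3"]
        + list(rng.choice(pool, 6, replace=False)),
    }
    for i in range(18):
        sets[f"RANDOM_SET_{i:02d}"] = list(rng.choice(pool, 8, replace=False))
    return sets


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    counts_path = ROOT / "results" / "cohort_counts.tsv"
    rec_path = ROOT / "results" / "truth_records.tsv"
    meta_path = ROOT / "results" / "cohort_metadata.tsv"
    if not (counts_path.exists() and rec_path.exists()):
        raise SystemExit("run analysis/01 and 02 first")
    cohort = pd.read_csv(counts_path, sep="\t")
    truth = SyntheticTruth(
        samples=pd.read_csv(meta_path, sep="\t"),
        event_labels={},
        records=pd.read_csv(rec_path, sep="\t"),
    )
    design = build_default_design()

    patients = truth.samples.loc[truth.samples.group != "HC", "sample_id"].tolist()
    npx = simulate_npx(design, truth, seed=args.seed, samples=patients)
    (ROOT / "scratch").mkdir(exist_ok=True)
    npx.to_long_csv(ROOT / "scratch" / "npx_long.csv")
    filt = qc_filter(npx)
    print(f"QC: {npx.n_assays} assays, {filt.n_assays} retained "
          f"({100 * filt.n_assays / npx.n_assays:.0f}%)")
    lost = [a for a in design.npx_effects if a not in filt.values.index]
    if lost:
        print(f"note: effect protein(s) removed by QC this run: {', '.join(lost)}")

    contrast = filt.sample_meta["detectable_cdh11_fib"].to_numpy()
    print(f"contrast: {contrast.sum()} patients with detectable CDH11+ fibroblasts "
          f"vs {(~contrast).sum()} without")
    de = differential_expression(filt, contrast)
    de.table.sort_values("p_adj").to_csv(ROOT / "results" / "de_results.tsv", sep="\t")
    deps = select_deps(de)
    print(f"DEPs (p_adj<0.05, |log2FC|>1): {', '.join(deps.index) or 'none'}")

    rng = np.random.default_rng(args.seed)
    sets = synthetic_gene_sets(list(filt.values.index), rng)
    enr = preranked_gsea(de.table["t_moderated"], sets, n_perm=2000, seed=args.seed)
    enr_df = pd.DataFrame([{"set": e.set_name, "es": e.es, "nes": e.nes,
                            "p": e.p, "p_adj": e.adjusted_p, "size": e.size}
                           for e in enr]).sort_values("p_adj")
    enr_df.to_csv(ROOT / "results" / "enrichment.tsv", sep="\t", index=False)
    sig = enr_df[enr_df.p_adj < 0.05]
    print("significantly enriched sets:")
    print(sig.to_string(index=False) if len(sig) else "  none")

    sig_proteins = sorted({g for e in enr if e.adjusted_p is not None and e.adjusted_p < 0.05
                           for g in sets[e.set_name]})
    if not sig_proteins:
        print("no enriched set at p_adj<0.05; screening the DEPs instead")
        sig_proteins = list(deps.index)
    counts = cohort.set_index("sample_id").loc[
        [s for s in patients if s in set(cohort.sample_id)],
        ["fibroblast_count", "fibrocyte_count"]].T
    corr = protein_cell_correlation(filt, counts, protein_subset=sig_proteins, alpha=0.1)
    corr.sort_values("p_adj").to_csv(ROOT / "results" / "correlations.tsv", sep="\t",
                                     index=False)
    print(f"correlation screen: {len(corr)} pairs, "
          f"{int(corr['significant'].sum())} significant at adjusted p<0.1")


if __name__ == "__main__":
    main()
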