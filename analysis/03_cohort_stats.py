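#!/usr/bin/env python
"""Group comparisons on the gated cohort counts.

Kruskal-Wallis across HC/RA/PsA with BKY-corrected pairwise post-hoc
comparisons, Mann-Whitney for HC vs merged patients, and Fisher's exact
test on the >=1-fibroblast detection table. Writes results/stats.tsv.
"""

from pathlib import Path

import pandas as pd

from fibrocyto.phenotype import detection_summary
from fibrocyto.stats import fisher_exact, kruskal_wallis, mann_whitney, pairwise_posthoc

ROOT = Path(__file__).resolve().parents[1]


def main():
    path = ROOT / "results" / "cohort_counts.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_gate_and_enumerate.py first")
    cohort = pd.read_csv(path, sep="\t")

    rows = []
    for qty in ("fibroblast_count", "fibrocyte_count"):
        groups = {g: sub[qty].to_numpy() for g, sub in cohort.groupby("group")}
        kw = kruskal_wallis(list(groups.values()))
        rows.append({"quantity": qty, "comparison": "HC vs RA vs PsA",
                     "method": kw.method, "statistic": kw.statistic, "p": kw.p,
                     "p_adj": None})
        for r in pairwise_posthoc(groups):
            rows.append({"quantity": qty, "comparison": r.notes["comparison"],
                         "method": r.method + "+bky", "statistic": r.statistic,
                         "p": r.p, "p_adj": r.adjusted_p})
        hc = cohort.loc[cohort.group == "HC", qty].to_numpy()
        pat = cohort.loc[cohort.group != "HC", qty].to_numpy()
        mw = mann_whitney(hc, pat)
        rows.append({"quantity": qty, "comparison": "HC vs RA+PsA",
                     "method": mw.method, "statistic": mw.statistic, "p": mw.p,
                     "p_adj": None})

    _, t22 = detection_summary(cohort, min_count=1)
    fe = fisher_exact(t22)
    rows.append({"quantity": "fibroblast_detected", "comparison": "patients vs controls",
                 "method": fe.method, "statistic": fe.statistic, "p": fe.p,
                 "p_adj": None})

    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "results" / "stats.tsv", sep="\t", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nwritten to results/stats.tsv")


if __name__ == "__main__":
    main()
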