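#!/usr/bin/env python
"""Simulate the default 32-sample whole-blood cohort (9 HC, 11 RA, 12 PsA).

Writes one FCS 3.1 file per sample under scratch/cohort/ and the ground
truth (spiked-cell records, sample metadata) under results/. Bulk size is
reduced to 50,000 events/sample; rare-cell content is unaffected by bulk
size. Usage: python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

from fibrocyto.design import AcquisitionModel, build_default_design
from fibrocyto.fcs import write_fcs
from fibrocyto.simulate import simulate_cohort, write_truth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--events", type=int, default=50_000)
    args = ap.parse_args()

    design = build_default_design()
    acq = AcquisitionModel(target_events=args.events)
    tables, truth = simulate_cohort(design, acq, seed=args.seed)

    fcs_dir = ROOT / "scratch" / "cohort"
    fcs_dir.mkdir(parents=True, exist_ok=True)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for t in tables:
        write_fcs(t, fcs_dir / f"{t.sample_id}.fcs")
    write_truth(truth, out / "truth_records.tsv", out / "cohort_metadata.tsv")

    n_fib = (truth.records.cell_class == "fibroblast").sum()
    n_fc = (truth.records.cell_class == "fibrocyte").sum()
    print(f"wrote {len(tables)} samples to {fcs_dir}")
    print(f"spiked ground truth: {n_fib} fibroblasts, {n_fc} fibrocytes "
          f"across {len(tables)} samples -> {out}/truth_records.tsv")


if __name__ == "__main__":
    main()
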