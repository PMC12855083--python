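"""End-to-end parameter-recovery studies on synthetic cohorts.

Each function simulates under the default study conditions, runs the gating
and enumeration pipeline, and returns the recovered quantity next to the
generating truth. These drive both the test suite and the reproduction
script, so the simulation sizes live here in one place.

Bulk-event counts are configurable; rare-cell recovery depends only on the
spike rate and analyzed volume, so the recovery studies run at reduced bulk
sizes (10-20k events/sample) while single-sample fraction checks use the
full 500k-event acquisition.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .design import AcquisitionModel, build_default_design
from .gating import (
    GatingConfig,
    gate_fibroblasts,
    gate_fibrocytes,
    gate_intact_singlets,
    gate_leukocyte_subsets,
    coexpression_counts,
)
from .phenotype import estimate_cells_per_ml
from .simulate import simulate_sample

#: The 23 patient samples of the cohort: 11 RA followed by 12 PsA.
PATIENT_SLOTS = ("RA",) * 11 + ("PsA",) * 12


def gate_rare_cells(table, config: GatingConfig | None = None):
    """Singlet cleanup plus both rare-cell gates for one sample."""
    config = config or GatingConfig()
    labels = gate_intact_singlets(table, config)
    fb = gate_fibroblasts(table, config, labels)
    fc = gate_fibrocytes(table, config, labels)
    return fb, fc, labels


def patient_cohort_median_frequencies(
    seed: int,
    n_replicates: int = 10,
    target_events: int = 20_000,
) -> dict[str, np.ndarray]:
    """Cohort-median recovered cells/ml for fibroblasts and fibrocytes.

    Simulates ``n_replicates`` independent 23-patient cohorts at the default
    patient spike rates (7 and 70 cells/ml), gates every sample, and returns
    the per-replicate cohort medians of the estimated frequencies.
    """
    design = build_default_design()
    acq = AcquisitionModel(target_events=target_events)
    fb_medians, fc_medians = [], []
    for rep in range(n_replicates):
        fb_per_ml, fc_per_ml = [], []
        for k, group in enumerate(PATIENT_SLOTS):
            child = np.random.SeedSequence([int(seed), rep, k])
            table, _ = simulate_sample(design, acq, group=group, seed=child,
                                       sample_id=f"rep{rep}-{group}{k}")
            fb, fc, _ = gate_rare_cells(table)
            fb_per_ml.append(estimate_cells_per_ml(len(fb), table.effective_volume_ml))
            fc_per_ml.append(estimate_cells_per_ml(len(fc), table.effective_volume_ml))
        fb_medians.append(float(np.median(fb_per_ml)))
        fc_medians.append(float(np.median(fc_per_ml)))
    return {"fibroblast_medians": np.array(fb_medians),
            "fibrocyte_medians": np.array(fc_medians)}


def bone_marrow_blood_ratio(
    seed: int, n_patients: int = 2, target_events: int = 10_000
) -> float:
    """Pooled bone-marrow:blood fibrocyte frequency ratio for one replicate.

    Mirrors the paired-sample comparison (two patients with matched blood
    and bone-marrow draws): fibrocytes are gated in each tissue and the
    per-ml estimates pooled over patients before taking the ratio.
    """
    design = build_default_design()
    acq = AcquisitionModel(target_events=target_events)
    blood = marrow = 0
    for k in range(n_patients):
        for i, tissue in enumerate(("blood", "bone_marrow")):
            child = np.random.SeedSequence([int(seed), k, i])
            table, _ = simulate_sample(design, acq, group="PsA", tissue=tissue,
                                       seed=child, sample_id=f"pair{k}-{tissue}")
            _, fc, _ = gate_rare_cells(table)
            if tissue == "blood":
                blood += len(fc)
            else:
                marrow += len(fc)
    return marrow / blood if blood else float("inf")


def replicate_bm_ratios(seed: int, n_replicates: int = 100, **kwargs) -> np.ndarray:
    return np.array(
        [bone_marrow_blood_ratio(int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31),
                                 **kwargs)
         for r in range(n_replicates)]
    )


def cd45_double_positive_recovery(
    seed: int, fraction: float = 0.01, target_events: int = 500_000
) -> dict[str, float]:
    """Recovered CDH11+CD90+ fraction of CD45+ events at a known spike fraction."""
    design = replace(build_default_design(), cdh11_cd90_leukocyte_fraction=fraction)
    acq = AcquisitionModel(target_events=target_events)
    table, truth = simulate_sample(design, acq, group="RA", seed=seed,
                                   sample_id="dp-recovery")
    config = GatingConfig()
    labels = gate_leukocyte_subsets(table, config)
    _, frac = coexpression_counts(labels, table, config)
    n_cd45 = int((labels.is_intact & labels.is_cd45).sum())
    return {"recovered_fraction": frac, "true_fraction": fraction, "n_cd45": n_cd45}


def neutrophil_coexpression_recovery(
    seed: int, fraction: float = 0.042, n_neutrophils: int = 10_000
) -> dict[str, float]:
    """Recovered CDH11+CD90+ proportion in a pure-neutrophil sample.

    Emulates the tissue quantification setting: a fixed number of
    neutrophil events with a known double-positive proportion and nothing
    else in the acquisition.
    """
    design = replace(
        build_default_design(),
        leukocyte_mix={"neutrophil": 1.0},
        fibroblast_rate={"HC": 0.0, "RA": 0.0, "PsA": 0.0},
        fibrocyte_rate={"HC": 0.0, "RA": 0.0, "PsA": 0.0},
        cdh11_cd90_leukocyte_fraction=fraction,
    )
    acq = AcquisitionModel(target_events=n_neutrophils, bead_fraction=0.0,
                           debris_fraction=0.0, doublet_fraction=0.0)
    table, _ = simulate_sample(design, acq, group="RA", seed=seed,
                               sample_id="neutrophil-recovery")
    config = GatingConfig()
    labels = gate_leukocyte_subsets(table, config)
    coex, _ = coexpression_counts(labels, table, config)
    row = coex.set_index("subset").loc["neutrophil"]
    n = int(row["n_events"])
    return {
        "recovered_percent": 100.0 * row["cdh11_cd90"] / n if n else float("nan"),
        "true_percent": 100.0 * fraction,
        "n_neutrophils": n,
    }


def distinct_subset_count(seed: int, target_events: int = 100_000) -> int:
    """Number of distinct leukocyte labels the tree produces on an all-lineage sample."""
    design = build_default_design()
    acq = AcquisitionModel(target_events=target_events)
    table, _ = simulate_sample(design, acq, group="RA", seed=seed,
                               sample_id="all-lineage")
    labels = gate_leukocyte_subsets(table, GatingConfig())
    found = set(labels.lineage[labels.is_intact & labels.is_cd45]) - {"unassigned"}
    return len(found)
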