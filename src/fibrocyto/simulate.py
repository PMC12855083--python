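"""Synthetic whole-blood / bone-marrow CyTOF cohorts with known ground truth.

One simulated acquisition is a mixture of event blocks — calibration beads,
DNA-low debris, summed-pair doublets, bulk leukocytes realizing the lineage
mixture, and the spiked rare cells — shuffled into a random acquisition
order. Spike counts per rare-cell class are Poisson(rate x V_eff), the
counting law for cells captured from a fixed analyzed blood volume. Marker
intensities follow the acquisition noise model: positive states draw from a
zero-inflated log-normal (raw median ~100 counts), negative states from an
exponential background tail, giving the clean marker separation threshold
gating relies on. Every spiked cell and every bulk event carries a truth
record, so gate sensitivity and specificity are measurable exactly.

Per-sample seeds derive from the master seed through a fixed counter scheme
(``SeedSequence([master_seed, sample_counter])``), so any one sample of a
cohort can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    AcquisitionModel,
    CohortDesign,
    DesignError,
    FIBROBLAST_BASIS,
    FIBROCYTE_BASIS,
    LEUKOCYTE_SUBSETS,
)
from .fcs import EventTable
from .panel import CHEMOKINE_RECEPTORS, default_panel
from .phenotype import decode_phenotype

#: Markers each bulk lineage stains positive for (plus CD45 on all of them).
LINEAGE_SIGNATURES: dict[str, tuple[str, ...]] = {
    "neutrophil": ("CD66b", "CD16"),
    "eosinophil": ("CD66b", "CD294"),
    "basophil": ("CD294",),
    "monocyte": ("CD14", "CD33", "HLA-DR"),
    "NK": ("CD56", "CD16"),
    "DC": ("HLA-DR",),
    "ILC": ("CD127",),
    "MAIT_iNKT": ("CD3", "Va7.2"),
    "gdT": ("CD3", "TCRgd"),
    "CD4T": ("CD3", "CD4"),
    "CD8T": ("CD3", "CD8"),
    "B": ("CD19", "HLA-DR"),
}

RARE_CLASSES = ("fibroblast", "fibrocyte")


@dataclass
class SyntheticTruth:
    """Ground truth for one or more simulated samples."""

    samples: pd.DataFrame  # sample_id, group, tissue, timepoint, V_eff
    event_labels: dict[str, pd.DataFrame]  # sample_id -> (cls, cdh11_cd90) per event
    records: pd.DataFrame  # one row per spiked rare cell
    npx_effects: pd.DataFrame | None = None

    def spiked_count(self, sample_id: str, cell_class: str) -> int:
        r = self.records
        return int(((r["sample_id"] == sample_id) & (r["cell_class"] == cell_class)).sum())

    def detectable_cdh11_fibroblasts(self) -> pd.Series:
        """Per-sample indicator: truth contains >= 1 CDH11+ fibroblast."""
        r = self.records
        hit = r[(r["cell_class"] == "fibroblast") & r["CDH11"]]
        ids = self.samples["sample_id"]
        return pd.Series(ids.isin(hit["sample_id"]).to_numpy(), index=ids.to_numpy(), name="detectable")

    @staticmethod
    def empty() -> "SyntheticTruth":
        return SyntheticTruth(
            samples=pd.DataFrame(columns=["sample_id", "group", "tissue", "timepoint",
                                          "effective_volume_ml"]),
            event_labels={},
            records=_empty_records(),
        )

    @staticmethod
    def merge(parts: list["SyntheticTruth"]) -> "SyntheticTruth":
        if not parts:
            return SyntheticTruth.empty()
        labels: dict[str, pd.DataFrame] = {}
        for p in parts:
            labels.update(p.event_labels)
        return SyntheticTruth(
            samples=pd.concat([p.samples for p in parts], ignore_index=True),
            event_labels=labels,
            records=pd.concat([p.records for p in parts], ignore_index=True),
        )


_RECORD_COLUMNS = (
    ["sample_id", "event_index", "cell_class", "phenotype_code"]
    + ["CDH11", "PDPN", "CD34", "CD90", "Notch3", "HLA-DR"]
    + list(CHEMOKINE_RECEPTORS)
)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=_RECORD_COLUMNS)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _positive_block(rng, acq: AcquisitionModel, shape) -> np.ndarray:
    x = rng.lognormal(np.log(acq.positive_median), acq.positive_sigma, size=shape)
    if acq.zero_inflation > 0:
        x = x * (rng.random(shape) >= acq.zero_inflation)
    return x


def _intensities(rng, acq: AcquisitionModel, positive: np.ndarray) -> np.ndarray:
    """Raw counts for a Boolean positivity matrix."""
    neg = rng.exponential(acq.background_scale, size=positive.shape)
    out = np.where(positive, _positive_block(rng, acq, positive.shape), neg)
    return out


def _sample_codes(rng, mixture: dict[int, float], n: int) -> np.ndarray:
    codes = np.fromiter(mixture.keys(), dtype=int)
    weights = np.fromiter(mixture.values(), dtype=float)
    return codes[rng.choice(len(codes), size=n, p=weights / weights.sum())]


def simulate_sample(
    design: CohortDesign,
    acq: AcquisitionModel | None = None,
    group: str = "RA",
    tissue: str = "blood",
    seed=0,
    sample_id: str | None = None,
    timepoint: str = "baseline",
) -> tuple[EventTable, SyntheticTruth]:
    """Simulate one acquisition; identical seeds give identical output."""
    acq = acq or AcquisitionModel()
    if group not in design.fibroblast_rate or group not in design.fibrocyte_rate:
        raise DesignError(f"group {group!r} not defined in the design")
    if tissue not in ("blood", "bone_marrow"):
        raise DesignError(f"unknown tissue {tissue!r} (blood or bone_marrow)")
    rng = _rng(seed)
    panel = default_panel()
    sample_id = sample_id or f"{group}-{tissue}-s{seed if isinstance(seed, int) else 'x'}"
    v_eff = acq.effective_volume_ml

    fib_rate = design.fibroblast_rate[group]
    fc_rate = design.fibrocyte_rate[group]
    if tissue == "bone_marrow":
        fc_rate *= design.bone_marrow_fibrocyte_fold
    n_fib = int(rng.poisson(fib_rate * v_eff))
    n_fc = int(rng.poisson(fc_rate * v_eff))

    n_target = acq.target_events
    n_bead = int(round(acq.bead_fraction * n_target))
    n_debris = int(round(acq.debris_fraction * n_target))
    n_doublet = int(round(acq.doublet_fraction * n_target))
    n_leuk = max(0, n_target - n_bead - n_debris - n_doublet - n_fib - n_fc)

    markers = [c.marker for c in panel.channels
               if c.role in ("lineage", "mesenchymal", "chemokine")]
    m_idx = {m: j for j, m in enumerate(markers)}
    n_markers = len(markers)

    def cell_rows(positive: np.ndarray) -> np.ndarray:
        """Full channel rows for cell-derived singlet events."""
        n = positive.shape[0]
        x = np.empty((n, len(panel)), dtype=float)
        x[:, [panel.index(m) for m in markers]] = _intensities(rng, acq, positive)
        for dna in panel.dna_markers:
            x[:, panel.index(dna)] = rng.lognormal(np.log(acq.dna_median), acq.dna_sigma, n)
        for bead in panel.bead_markers:
            x[:, panel.index(bead)] = rng.exponential(acq.background_scale, n)
        x[:, panel.index(panel.event_length_marker)] = np.clip(
            rng.normal(acq.event_length_mean, acq.event_length_sd, n), 1, None
        )
        return x

    def leukocyte_positivity(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mix_names = list(design.leukocyte_mix)
        probs = np.array([design.leukocyte_mix[s] for s in mix_names])
        lineage_idx = rng.choice(len(mix_names), size=n, p=probs / probs.sum())
        sig = np.zeros((len(mix_names), n_markers), dtype=bool)
        for i, s in enumerate(mix_names):
            sig[i, m_idx["CD45"]] = True
            for m in LINEAGE_SIGNATURES[s]:
                sig[i, m_idx[m]] = True
        positive = sig[lineage_idx]
        dp = rng.random(n) < design.cdh11_cd90_leukocyte_fraction
        positive[dp, m_idx["CDH11"]] = True
        positive[dp, m_idx["CD90"]] = True
        n_dp = int(dp.sum())
        positive[np.flatnonzero(dp)[rng.random(n_dp) < design.leukocyte_notch3_prob],
                 m_idx["Notch3"]] = True
        for r in CHEMOKINE_RECEPTORS:
            p = design.receptor_prob(group, "leukocyte", r)
            positive[np.flatnonzero(dp)[rng.random(n_dp) < p], m_idx[r]] = True
        return positive, np.array(mix_names, dtype=object)[lineage_idx], dp

    blocks: list[np.ndarray] = []
    cls: list[np.ndarray] = []
    dp_flags: list[np.ndarray] = []
    record_rows: list[dict] = []
    cursor = 0  # event index in pre-shuffle order

    def push(x: np.ndarray, label, dp=None):
        nonlocal cursor
        blocks.append(x)
        if isinstance(label, np.ndarray):
            cls.append(label)
        else:
            cls.append(np.full(len(x), label, dtype=object))
        dp_flags.append(np.zeros(len(x), dtype=bool) if dp is None else dp)
        start = cursor
        cursor += len(x)
        return start

    # --- calibration beads -------------------------------------------------
    if n_bead:
        x = np.empty((n_bead, len(panel)), dtype=float)
        marker_cols = [panel.index(m) for m in markers]
        x[:, marker_cols] = rng.exponential(acq.background_scale, (n_bead, n_markers))
        for dna in panel.dna_markers:
            x[:, panel.index(dna)] = rng.exponential(acq.background_scale, n_bead)
        for bead in panel.bead_markers:
            x[:, panel.index(bead)] = rng.lognormal(np.log(acq.bead_median), acq.bead_sigma, n_bead)
        x[:, panel.index(panel.event_length_marker)] = np.clip(rng.normal(25, 3, n_bead), 1, None)
        push(x, "bead")

    # --- debris ------------------------------------------------------------
    if n_debris:
        x = np.empty((n_debris, len(panel)), dtype=float)
        marker_cols = [panel.index(m) for m in markers]
        x[:, marker_cols] = rng.exponential(acq.background_scale, (n_debris, n_markers))
        for dna in panel.dna_markers:
            x[:, panel.index(dna)] = rng.exponential(acq.debris_dna_scale, n_debris)
        for bead in panel.bead_markers:
            x[:, panel.index(bead)] = rng.exponential(acq.background_scale, n_debris)
        x[:, panel.index(panel.event_length_marker)] = np.clip(rng.normal(20, 3, n_debris), 1, None)
        push(x, "debris")

    # --- doublets: summed pairs of bulk leukocyte events --------------------
    if n_doublet:
        pos, _, _ = leukocyte_positivity(2 * n_doublet)
        pair = cell_rows(pos)
        push(pair[:n_doublet] + pair[n_doublet:], "doublet")

    # --- bulk leukocytes ----------------------------------------------------
    if n_leuk:
        pos, lineage, dp = leukocyte_positivity(n_leuk)
        push(cell_rows(pos), lineage, dp)

    # --- spiked rare cells --------------------------------------------------
    def spike(cell_class: str, n: int, mixture: dict[int, float], basis) -> None:
        if not n:
            return
        pos = np.zeros((n, n_markers), dtype=bool)
        codes = _sample_codes(rng, mixture, n)
        flags = {m: np.zeros(n, dtype=bool) for m in
                 ("CDH11", "PDPN", "CD34", "CD90", "Notch3", "HLA-DR")}
        for m in basis:
            flags[m] = np.array([decode_phenotype(c, basis)[m] for c in codes])
        if cell_class == "fibroblast":
            flags["PDPN"] = np.ones(n, dtype=bool)
            p_dr = design.fibroblast_hladr_prob.get(group, 0.0)
            flags["HLA-DR"] = rng.random(n) < p_dr
        else:  # fibrocyte: CD34 and HLA-DR by definition, CD45 positive
            flags["CD34"] = np.ones(n, dtype=bool)
            flags["HLA-DR"] = np.ones(n, dtype=bool)
            pos[:, m_idx["CD45"]] = True
        for m, v in flags.items():
            pos[:, m_idx[m]] = v
        receptor_flags = {}
        for r in CHEMOKINE_RECEPTORS:
            p = design.receptor_prob(group, cell_class, r)
            receptor_flags[r] = rng.random(n) < p
            pos[:, m_idx[r]] = receptor_flags[r]
        start = push(cell_rows(pos), cell_class)
        for i in range(n):
            row = {"sample_id": sample_id, "event_index": start + i,
                   "cell_class": cell_class, "phenotype_code": int(codes[i])}
            row.update({m: bool(flags[m][i]) for m in flags})
            row.update({r: bool(receptor_flags[r][i]) for r in CHEMOKINE_RECEPTORS})
            record_rows.append(row)

    spike("fibroblast", n_fib, design.fibroblast_mixture[group], FIBROBLAST_BASIS)
    spike("fibrocyte", n_fc, design.fibrocyte_mixture[group], FIBROCYTE_BASIS)

    if blocks:
        data = np.concatenate(blocks)
        cls_arr = np.concatenate(cls)
        dp_arr = np.concatenate(dp_flags)
    else:
        data = np.zeros((0, len(panel)))
        cls_arr = np.zeros(0, dtype=object)
        dp_arr = np.zeros(0, dtype=bool)

    # shuffle into acquisition order, then apply any sensitivity drift
    n_total = len(data)
    perm = rng.permutation(n_total)
    data, cls_arr, dp_arr = data[perm], cls_arr[perm], dp_arr[perm]
    new_pos = np.empty(n_total, dtype=int)
    new_pos[perm] = np.arange(n_total)
    for row in record_rows:
        row["event_index"] = int(new_pos[row["event_index"]])

    if acq.sensitivity_decay > 0 and n_total > 1:
        factor = 1.0 - acq.sensitivity_decay * np.arange(n_total) / (n_total - 1)
        ev_len = panel.index(panel.event_length_marker)
        chan = [i for i in range(len(panel)) if i != ev_len]
        data[:, chan] *= factor[:, None]

    table = EventTable(
        sample_id=sample_id,
        data=data,
        panel=panel,
        stained_volume_ml=acq.stained_volume_ml,
        acquisition_fraction=acq.acquisition_fraction,
    )
    records = pd.DataFrame(record_rows, columns=_RECORD_COLUMNS) if record_rows else _empty_records()
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            [{"sample_id": sample_id, "group": group, "tissue": tissue,
              "timepoint": timepoint, "effective_volume_ml": v_eff}]
        ),
        event_labels={sample_id: pd.DataFrame({"cls": cls_arr, "cdh11_cd90": dp_arr})},
        records=records,
    )
    return table, truth


def simulate_cohort(
    design: CohortDesign, acq: AcquisitionModel | None = None, seed: int = 0
) -> tuple[list[EventTable], SyntheticTruth]:
    """One blood sample per design slot; per-sample seeds are counter-derived."""
    acq = acq or AcquisitionModel()
    tables: list[EventTable] = []
    truths: list[SyntheticTruth] = []
    counter = 0
    for group, size in design.group_sizes.items():
        for i in range(size):
            child = np.random.SeedSequence([int(seed), counter])
            t, tr = simulate_sample(
                design, acq, group=group, tissue="blood", seed=child,
                sample_id=f"{group}{i + 1:02d}",
            )
            tables.append(t)
            truths.append(tr)
            counter += 1
    return tables, SyntheticTruth.merge(truths)


def simulate_npx(
    design: CohortDesign, cohort_truth: SyntheticTruth, seed: int = 0,
    samples: list[str] | None = None,
):
    """Olink-style NPX matrix tied to the cohort's fibroblast ground truth.

    368 assays per sample on a log2 scale; designated effect proteins are
    shifted by their design effect in samples whose truth contains at least
    one CDH11+ fibroblast; ``npx_n_flagged`` assays carry a QC warning.
    """
    from .proteomics import NPXMatrix

    known = list(cohort_truth.samples["sample_id"])
    if samples is None:
        samples = known
    missing = [s for s in samples if s not in known]
    if missing:
        raise ValueError(f"samples absent from the cohort truth: {missing}")
    rng = _rng(np.random.SeedSequence([int(seed), 368]))
    assays = list(design.npx_assays)
    detect = cohort_truth.detectable_cdh11_fibroblasts().reindex(samples)
    groups = cohort_truth.samples.set_index("sample_id")["group"].reindex(samples)

    baseline = rng.normal(5.0, 1.5, size=len(assays))
    effects = np.array([design.npx_effects.get(a, 0.0) for a in assays])
    noise = rng.normal(0.0, design.npx_noise_sd, size=(len(assays), len(samples)))
    values = baseline[:, None] + np.outer(effects, detect.to_numpy().astype(float)) + noise

    flagged = np.zeros(len(assays), dtype=bool)
    if design.npx_n_flagged:
        flagged[rng.choice(len(assays), size=design.npx_n_flagged, replace=False)] = True
    lod = baseline - 4.0
    below = (values < lod[:, None]).mean(axis=1)

    vdf = pd.DataFrame(values, index=pd.Index(assays, name="assay"), columns=samples)
    qc = pd.DataFrame({"warning": flagged, "below_lod_frac": below, "lod": lod},
                      index=vdf.index)
    meta = pd.DataFrame({"group": groups.to_numpy(), "detectable_cdh11_fib": detect.to_numpy()},
                        index=pd.Index(samples, name="sample_id"))
    truth_effects = pd.DataFrame({"assay": assays, "log2_effect": effects})
    cohort_truth.npx_effects = truth_effects
    return NPXMatrix(values=vdf, assay_qc=qc, sample_meta=meta)


# ---------------------------------------------------------------------------
# plain-text truth / metadata export
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, records_path, samples_path) -> None:
    truth.records.to_csv(records_path, sep="\t", index=False)
    truth.samples.to_csv(samples_path, sep="\t", index=False)


def read_truth_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
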