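"""Cohort and acquisition ground-truth designs for the synthetic generator.

``CohortDesign`` encodes the study conditions the generator reproduces:
group sizes (9 controls, 11 RA, 12 PsA), rare-cell spike rates (circulating
fibroblasts at a median 7 cells/ml in patients, fibrocytes at 70 cells/ml,
50-100x more abundant in bone marrow), the mixture of the 16 mesenchymal
marker combinations per group, chemokine-receptor positivity, the whole-blood
leukocyte lineage mixture, and the ~1% CDH11+CD90+ fraction of CD45+ cells.

``AcquisitionModel`` encodes how much blood reaches the instrument (270 ul
stained, acquisition fraction) and the intensity noise model: positive marker
states are zero-inflated log-normal (raw median ~100 dual counts), negative
states an exponential background tail (~0-2 counts). The effective analyzed
volume is V_eff = stained_volume_ml * acquisition_fraction, so an expected
spike count is rate * V_eff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import CHEMOKINE_RECEPTORS

GROUPS = ("HC", "RA", "PsA")
PATIENT_GROUPS = ("RA", "PsA")

#: Fibroblast combination basis (bit order: first marker = least significant).
FIBROBLAST_BASIS = ("CDH11", "CD34", "CD90", "Notch3")
#: Fibrocyte combination basis.
FIBROCYTE_BASIS = ("CDH11", "PDPN", "CD90", "Notch3")

LEUKOCYTE_SUBSETS = (
    "neutrophil",
    "eosinophil",
    "basophil",
    "monocyte",
    "NK",
    "DC",
    "ILC",
    "MAIT_iNKT",
    "gdT",
    "CD4T",
    "CD8T",
    "B",
)


class DesignError(ValueError):
    """Raised on an invalid cohort or acquisition configuration."""


def _check_mixture(weights: dict[int, float], what: str) -> None:
    if any(w < 0 for w in weights.values()):
        raise DesignError(f"{what}: negative mixture weight")
    if any(not (1 <= c <= 16) for c in weights):
        raise DesignError(f"{what}: phenotype codes must be in 1..16")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise DesignError(f"{what}: mixture weights sum to {total}, not 1")


@dataclass
class AcquisitionModel:
    """Instrument-side parameters for one acquisition run."""

    stained_volume_ml: float = 0.27
    acquisition_fraction: float = 1.0
    target_events: int = 500_000
    leukocyte_density_per_ml: float = 5e6
    bead_fraction: float = 0.03
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.02
    sensitivity_decay: float = 0.0  # fractional linear loss over the run

    # intensity noise model (raw dual-count scale)
    positive_median: float = 100.0
    positive_sigma: float = 0.5  # log-normal sigma (natural log)
    background_scale: float = 0.5  # exponential tail of negative states
    zero_inflation: float = 0.0  # P(positive state reads 0)
    dna_median: float = 500.0
    dna_sigma: float = 0.15
    debris_dna_scale: float = 5.0
    bead_median: float = 1000.0
    bead_sigma: float = 0.02
    event_length_mean: float = 30.0
    event_length_sd: float = 4.0

    def __post_init__(self):
        for name in ("bead_fraction", "debris_fraction", "doublet_fraction",
                     "acquisition_fraction", "zero_inflation", "sensitivity_decay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DesignError(f"{name}={v} must be in [0, 1]")
        if self.stained_volume_ml <= 0:
            raise DesignError("stained_volume_ml must be > 0")
        if self.target_events <= 0:
            raise DesignError("target_events must be > 0")

    @property
    def effective_volume_ml(self) -> float:
        return self.stained_volume_ml * self.acquisition_fraction


@dataclass
class CohortDesign:
    """Generating parameters for one synthetic cohort."""

    group_sizes: dict[str, int]
    fibroblast_rate: dict[str, float]  # cells/ml by group
    fibrocyte_rate: dict[str, float]  # cells/ml by group
    bone_marrow_fibrocyte_fold: float
    fibroblast_mixture: dict[str, dict[int, float]]  # group -> code -> weight
    fibrocyte_mixture: dict[str, dict[int, float]]
    receptor_probs: dict[str, dict[str, float]]  # cell class -> receptor -> P
    group_receptor_overrides: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    fibroblast_hladr_prob: dict[str, float] = field(default_factory=dict)
    leukocyte_mix: dict[str, float] = field(default_factory=dict)
    cdh11_cd90_leukocyte_fraction: float = 0.01
    leukocyte_notch3_prob: float = 0.2
    npx_assays: tuple[str, ...] = ()
    npx_effects: dict[str, float] = field(default_factory=dict)  # log2 shift
    npx_noise_sd: float = 0.3
    npx_n_flagged: int = 10

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise DesignError(f"group {g}: sample size must be >= 1")
        for rates in (self.fibroblast_rate, self.fibrocyte_rate):
            for g, r in rates.items():
                if r < 0:
                    raise DesignError(f"group {g}: negative spike rate")
        if self.bone_marrow_fibrocyte_fold < 0:
            raise DesignError("bone_marrow_fibrocyte_fold must be >= 0")
        for g, w in self.fibroblast_mixture.items():
            _check_mixture(w, f"fibroblast mixture[{g}]")
        for g, w in self.fibrocyte_mixture.items():
            _check_mixture(w, f"fibrocyte mixture[{g}]")
        if self.leukocyte_mix:
            total = sum(self.leukocyte_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise DesignError(f"leukocyte_mix sums to {total}, not 1")
            if any(p < 0 for p in self.leukocyte_mix.values()):
                raise DesignError("leukocyte_mix: negative proportion")
        if not (0.0 <= self.cdh11_cd90_leukocyte_fraction <= 1.0):
            raise DesignError("cdh11_cd90_leukocyte_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def receptor_prob(self, group: str, cell_class: str, receptor: str) -> float:
        over = self.group_receptor_overrides.get(group, {}).get(cell_class, {})
        if receptor in over:
            return over[receptor]
        return self.receptor_probs.get(cell_class, {}).get(receptor, 0.0)


def _spread(codes: list[int], head: float) -> dict[int, float]:
    """Mixture putting ``head`` weight on the first code, the rest uniform."""
    rest = (1.0 - head) / (len(codes) - 1)
    return {codes[0]: head, **{c: rest for c in codes[1:]}}


def default_npx_assays(n: int = 368) -> tuple[str, ...]:
    """368-assay inflammation-panel namespace; the three effect proteins first."""
    named = ["CXCL1", "ANGPT1", "TIMP3"]
    return tuple(named + [f"PROT{i:04d}" for i in range(4, n + 1)])


def build_default_design() -> CohortDesign:
    """Design reproducing, in expectation, the reported cohort.

    Group sizes 9/11/12; patient fibroblast spike rate 7 cells/ml and
    fibrocyte rate 70 cells/ml (cohort medians); bone-marrow fibrocytes 70x
    blood (midpoint of the reported 50-100x range). Control fibroblasts never
    carry CDH11 or CD90 (those combinations have zero weight in HC), and
    control fibrocytes carry at most one mesenchymal marker. The fibroblast
    mixtures give 7 distinct combinations in RA, 6 in PsA and 2 in HC; the
    fibrocyte mixtures give 13/11/5.
    """
    # fibroblast codes over (CDH11, CD34, CD90, Notch3); code = 1 + sum b_i 2^i
    fb_ra = [1, 2, 3, 7, 8, 12, 16]  # 7 distinct combinations
    fb_psa = [1, 2, 5, 7, 12, 16]  # 6 distinct
    fb_hc = [1, 3]  # all-negative and CD34-only: no CDH11, no CD90
    # fibrocyte codes over (CDH11, PDPN, CD90, Notch3)
    fc_hc = [1, 2, 3, 5, 9]  # none + each single marker
    fc_ra = [c for c in range(1, 17) if c not in (4, 13, 15)]  # 13 distinct
    fc_psa = [c for c in range(1, 17) if c not in (4, 6, 13, 14, 15)]  # 11 distinct

    receptor_base = dict.fromkeys(CHEMOKINE_RECEPTORS, 0.0)
    return CohortDesign(
        group_sizes={"HC": 9, "RA": 11, "PsA": 12},
        fibroblast_rate={"HC": 1.6, "RA": 7.0, "PsA": 7.0},
        fibrocyte_rate={"HC": 50.0, "RA": 70.0, "PsA": 70.0},
        bone_marrow_fibrocyte_fold=70.0,
        fibroblast_mixture={"HC": _spread(fb_hc, 0.7), "RA": _spread(fb_ra, 0.3),
                            "PsA": _spread(fb_psa, 0.3)},
        fibrocyte_mixture={"HC": _spread(fc_hc, 0.5), "RA": _spread(fc_ra, 0.3),
                           "PsA": _spread(fc_psa, 0.3)},
        receptor_probs={
            "fibroblast": {**receptor_base, "CCR6": 0.6, "CCR7": 0.3, "CCR4": 0.2,
                           "CXCR3": 0.1, "CXCR5": 0.05},
            "fibrocyte": {**receptor_base, "CCR6": 0.6, "CCR7": 0.25, "CCR4": 0.2,
                          "CXCR3": 0.1, "CXCR5": 0.05},
            "leukocyte": {**receptor_base, "CCR6": 0.3, "CCR7": 0.2, "CCR4": 0.2,
                          "CXCR3": 0.1, "CXCR5": 0.05},
        },
        # CCR7 and HLA-DR on circulating fibroblasts were patient-exclusive
        group_receptor_overrides={"HC": {"fibroblast": {"CCR7": 0.0},
                                         "fibrocyte": {"CCR7": 0.1}}},
        fibroblast_hladr_prob={"HC": 0.0, "RA": 0.3, "PsA": 0.3},
        leukocyte_mix={
            "neutrophil": 0.55, "eosinophil": 0.03, "basophil": 0.01,
            "monocyte": 0.08, "NK": 0.05, "DC": 0.01, "ILC": 0.005,
            "MAIT_iNKT": 0.01, "gdT": 0.02, "CD4T": 0.12, "CD8T": 0.08, "B": 0.035,
        },
        cdh11_cd90_leukocyte_fraction=0.01,
        leukocyte_notch3_prob=0.2,
        npx_assays=default_npx_assays(368),
        npx_effects={"CXCL1": 2.0, "ANGPT1": 2.0, "TIMP3": 2.0},
        npx_noise_sd=0.3,
        npx_n_flagged=10,
    )
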