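"""Combinatorial phenotype codes, receptor profiles and per-ml frequencies.

Four binary mesenchymal markers span 16 combinations. The canonical code is

    code = 1 + sum_i b_i * 2**i

over the ordered basis (first marker = least significant bit), so code 1 is
the all-negative cell and code 16 the quadruple-positive. Fibroblasts are
coded over (CDH11, CD34, CD90, Notch3) and fibrocytes over
(CDH11, PDPN, CD90, Notch3). This binary order is defined by this package;
published FB1-16/FC1-16 labels from other sources need not follow it, so
only cardinalities of distinct phenotypes are comparable across codings.

Frequencies are absolute: a count of gated cells divided by the effective
analyzed blood volume V_eff gives cells per ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .design import FIBROBLAST_BASIS, FIBROCYTE_BASIS, LEUKOCYTE_SUBSETS
from .panel import CHEMOKINE_RECEPTORS

N_CODES = 16


def encode_phenotype(flags, basis=FIBROBLAST_BASIS) -> int:
    """Map 4 Boolean marker flags to the phenotype code 1-16."""
    flags = list(flags)
    if len(flags) != len(basis) or len(basis) != 4:
        raise ValueError(f"expected {len(basis)} flags for basis {basis}, got {len(flags)}")
    return 1 + sum(int(bool(b)) << i for i, b in enumerate(flags))


def decode_phenotype(code: int, basis=FIBROBLAST_BASIS) -> dict[str, bool]:
    """Inverse of :func:`encode_phenotype`."""
    if not 1 <= code <= N_CODES:
        raise ValueError(f"phenotype code must be in 1..16, got {code}")
    bits = code - 1
    return {m: bool((bits >> i) & 1) for i, m in enumerate(basis)}


def enumerate_phenotypes(records: pd.DataFrame, basis) -> pd.Series:
    """16-bin count table over phenotype codes for one cell class.

    ``records`` must carry one Boolean column per basis marker. The sum of
    bins equals the number of records; the number of nonzero bins is the
    count of distinct phenotypes observed.
    """
    counts = pd.Series(0, index=pd.RangeIndex(1, N_CODES + 1, name="code"), name="count")
    if len(records):
        codes = np.ones(len(records), dtype=int)
        for i, m in enumerate(basis):
            codes += records[m].to_numpy().astype(int) << i
        vc = pd.Series(codes).value_counts()
        counts.loc[vc.index] = vc.to_numpy()
    return counts


def distinct_phenotypes(counts: pd.Series) -> int:
    return int((counts > 0).sum())


def receptor_profile(records: pd.DataFrame, receptors=CHEMOKINE_RECEPTORS) -> pd.Series:
    """Positive-cell count per chemokine receptor (multi-positives count once per receptor)."""
    out = {}
    for r in receptors:
        if r not in records.columns and len(records):
            raise ValueError(f"unknown receptor {r!r}: not a column of the records")
        out[r] = int(records[r].sum()) if len(records) else 0
    return pd.Series(out, name="count")


def estimate_cells_per_ml(count: int, acq) -> float:
    """count / V_eff; ``acq`` is anything exposing ``effective_volume_ml``."""
    v_eff = acq.effective_volume_ml if hasattr(acq, "effective_volume_ml") else float(acq)
    if v_eff <= 0:
        raise ValueError(f"effective analyzed volume must be > 0, got {v_eff}")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count / v_eff


def round_percent(x: float) -> int:
    """Round half-up to integer percent (presentation convention)."""
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class SampleSummary:
    """Per-sample rare-cell and co-expression accounting."""

    sample_id: str
    group: str
    tissue: str = "blood"
    timepoint: str = "baseline"
    effective_volume_ml: float = 0.27
    fibroblast_count: int = 0
    fibrocyte_count: int = 0
    fibroblast_phenotypes: pd.Series | None = None
    fibrocyte_phenotypes: pd.Series | None = None
    fibroblast_receptors: pd.Series | None = None
    fibrocyte_receptors: pd.Series | None = None
    coexpression: pd.DataFrame | None = None  # per-subset CDH11+CD90+ counts
    cd45_double_positive_fraction: float = float("nan")

    @property
    def fibroblasts_per_ml(self) -> float:
        return estimate_cells_per_ml(self.fibroblast_count, self.effective_volume_ml)

    @property
    def fibrocytes_per_ml(self) -> float:
        return estimate_cells_per_ml(self.fibrocyte_count, self.effective_volume_ml)


def summarize_sample(
    table,
    labels,
    fibroblasts: pd.DataFrame,
    fibrocytes: pd.DataFrame,
    group: str,
    tissue: str = "blood",
    timepoint: str = "baseline",
    config=None,
) -> SampleSummary:
    """Assemble the full per-sample summary from gating outputs."""
    from .gating import GatingConfig, coexpression_counts

    config = config or GatingConfig()
    coex, frac = coexpression_counts(labels, table, config)
    return SampleSummary(
        sample_id=table.sample_id,
        group=group,
        tissue=tissue,
        timepoint=timepoint,
        effective_volume_ml=table.effective_volume_ml,
        fibroblast_count=len(fibroblasts),
        fibrocyte_count=len(fibrocytes),
        fibroblast_phenotypes=enumerate_phenotypes(fibroblasts, FIBROBLAST_BASIS),
        fibrocyte_phenotypes=enumerate_phenotypes(fibrocytes, FIBROCYTE_BASIS),
        fibroblast_receptors=receptor_profile(fibroblasts),
        fibrocyte_receptors=receptor_profile(fibrocytes),
        coexpression=coex,
        cd45_double_positive_fraction=frac,
    )


def cohort_table(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Stack per-sample summaries into a tidy cohort table."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "tissue": s.tissue,
                "timepoint": s.timepoint,
                "fibroblast_count": s.fibroblast_count,
                "fibrocyte_count": s.fibrocyte_count,
                "fibroblasts_per_ml": s.fibroblasts_per_ml,
                "fibrocytes_per_ml": s.fibrocytes_per_ml,
                "cd45_cdh11_cd90_fraction": s.cd45_double_positive_fraction,
            }
        )
    return pd.DataFrame(rows)


def detection_summary(cohort: pd.DataFrame, min_count: int = 1,
                      count_col: str = "fibroblast_count") -> tuple[pd.DataFrame, np.ndarray]:
    """Per-group proportion of samples with >= ``min_count`` detected cells.

    Also returns the 2x2 contingency table (detected vs not, patients vs
    controls) ready for an exact test. Percentages are reported raw and
    rounded half-up, matching how such detection rates are usually printed.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rows = []
    for g, sub in cohort.groupby("group", sort=False):
        k = int((sub[count_col] >= min_count).sum())
        n = len(sub)
        rows.append({"group": g, "n_detected": k, "n": n,
                     "proportion": k / n, "percent": round_percent(100 * k / n)})
    summary = pd.DataFrame(rows)
    is_patient = cohort["group"] != "HC"
    detected = cohort[count_col] >= min_count
    table22 = np.array(
        [
            [int((is_patient & detected).sum()), int((is_patient & ~detected).sum())],
            [int((~is_patient & detected).sum()), int((~is_patient & ~detected).sum())],
        ]
    )
    return summary, table22
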