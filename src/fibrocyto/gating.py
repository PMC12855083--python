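"""Hierarchical gating: event cleanup, leukocyte tree, rare-cell gates.

All positivity calls are made on the arcsinh-transformed scale
(``asinh(raw / cofactor)``, cofactor 5 by convention) against an explicit
threshold — the reproducible stand-in for manual 2-D gates. The default is a
fixed threshold of 1.5; a density-valley strategy (minimum of a smoothed 1-D
density between the two dominant modes) can be selected per config.

Gating proceeds as:

1. event cleanup — calibration beads (bead channel high, DNA low), debris
   (DNA below the intercalator window), doublets (DNA above the window, at
   roughly twice the singlet mode, or over-long events);
2. the 12-subset leukocyte tree on intact CD45+ singlets, first-match in a
   fixed, documented order;
3. rare-cell gates: circulating fibroblasts are PDPN+CD45- events negative
   for the full lineage-exclusion panel (CD3, CD19, CD4, CD8, CD56, CD66b,
   CD294); fibrocytes are CD34+HLA-DR+CD45+ events under the same exclusion.
   The two gates are disjoint by the CD45 requirement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fcs import EventTable
from .panel import CHEMOKINE_RECEPTORS, LINEAGE_EXCLUSION, PanelError


class GatingError(ValueError):
    pass


@dataclass
class GatingConfig:
    cofactor: float = 5.0
    default_threshold: float = 1.5  # transformed scale
    thresholds: dict[str, float] = field(default_factory=dict)  # per-marker overrides
    dna_window: tuple[float, float] = (4.5, 5.7)  # transformed; above = doublet
    length_window: tuple[float, float] = (10.0, 45.0)  # raw event length
    strategy: str = "fixed"  # or "density_valley"

    def __post_init__(self):
        if self.cofactor <= 0:
            raise GatingError("arcsinh cofactor must be > 0")
        if not np.isfinite(self.default_threshold):
            raise GatingError("threshold must be finite")
        for w in (self.dna_window, self.length_window):
            if not (w[0] < w[1]):
                raise GatingError(f"window bounds must be ordered, got {w}")
        if self.strategy not in ("fixed", "density_valley"):
            raise GatingError(f"unknown threshold strategy {self.strategy!r}")

    def config_hash(self) -> str:
        """Hash of the config plus the lineage-tree order, logged with results."""
        payload = {
            "cofactor": self.cofactor,
            "default_threshold": self.default_threshold,
            "thresholds": dict(sorted(self.thresholds.items())),
            "dna_window": list(self.dna_window),
            "length_window": list(self.length_window),
            "strategy": self.strategy,
            "tree": [name for name, _ in LINEAGE_TREE],
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


def transform_arcsinh(table: EventTable, cofactor: float = 5.0) -> EventTable:
    """Elementwise asinh(x / cofactor); monotone and invertible."""
    if cofactor <= 0:
        raise GatingError("arcsinh cofactor must be > 0")
    return replace(table, data=np.arcsinh(table.data / cofactor))


def inverse_arcsinh(table: EventTable, cofactor: float = 5.0) -> EventTable:
    if cofactor <= 0:
        raise GatingError("arcsinh cofactor must be > 0")
    return replace(table, data=np.sinh(table.data) * cofactor)


def density_valley_threshold(values: np.ndarray, fallback: float, bins: int = 256) -> float:
    """Minimum of a smoothed histogram between its two dominant modes.

    Falls back to the fixed threshold when the density is effectively
    unimodal (no valley to find).
    """
    v = values[np.isfinite(values)]
    if len(v) < 50 or v.min() == v.max():
        return fallback
    hist, edges = np.histogram(v, bins=bins)
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    peaks = [i for i in range(1, bins - 1) if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]]
    if len(peaks) < 2:
        return fallback
    top2 = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[valley])


class _Transformed:
    """Cached transformed marker columns plus positivity calls."""

    def __init__(self, table: EventTable, config: GatingConfig):
        self.table = table
        self.config = config
        self._cache: dict[str, np.ndarray] = {}

    def values(self, marker: str) -> np.ndarray:
        if marker not in self._cache:
            self._cache[marker] = np.arcsinh(self.table.marker(marker) / self.config.cofactor)
        return self._cache[marker]

    def threshold(self, marker: str) -> float:
        fixed = self.config.thresholds.get(marker, self.config.default_threshold)
        if self.config.strategy == "density_valley":
            return density_valley_threshold(self.values(marker), fixed)
        return fixed

    def positive(self, marker: str) -> np.ndarray:
        return self.values(marker) > self.threshold(marker)


@dataclass
class CellLabel:
    """Per-event assignments and cleanup flags for one sample."""

    lineage: np.ndarray  # str array; one of the 12 subsets or "unassigned"
    is_bead: np.ndarray
    is_debris: np.ndarray
    is_doublet: np.ndarray
    is_intact: np.ndarray  # intact singlet: none of the above
    is_cd45: np.ndarray  # CD45-positive call (only meaningful on intact events)
    config_hash: str = ""


def gate_intact_singlets(table: EventTable, config: GatingConfig | None = None) -> CellLabel:
    """Flag beads, debris and doublets; the rest are intact singlets.

    Debris: DNA (either iridium channel) below the window. Doublets: DNA
    above the window — the summed-event mode sits near twice the singlet
    mode — or event length beyond the singlet window.
    """
    config = config or GatingConfig()
    tr = _Transformed(table, config)
    panel = table.panel
    dna_markers = panel.dna_markers
    if len(dna_markers) != 2:
        raise PanelError("singlet gate requires two DNA channels")
    dna_lo, dna_hi = config.dna_window
    len_lo, len_hi = config.length_window

    dna = np.column_stack([tr.values(m) for m in dna_markers])
    length = table.marker(panel.event_length_marker)

    is_bead = np.zeros(table.n_events, dtype=bool)
    if panel.bead_markers:
        bead_hi = np.all(
            np.column_stack([tr.positive(m) for m in panel.bead_markers]), axis=1
        )
        is_bead = bead_hi & (dna < dna_lo).all(axis=1)
    is_debris = ~is_bead & (dna < dna_lo).any(axis=1)
    is_doublet = (
        ~is_bead
        & ~is_debris
        & ((dna > dna_hi).any(axis=1) | (length > len_hi) | (length < len_lo))
    )
    is_intact = ~(is_bead | is_debris | is_doublet)
    lineage = np.full(table.n_events, "unassigned", dtype="<U12")
    return CellLabel(
        lineage=lineage,
        is_bead=is_bead,
        is_debris=is_debris,
        is_doublet=is_doublet,
        is_intact=is_intact,
        is_cd45=np.zeros(table.n_events, dtype=bool),
        config_hash=config.config_hash(),
    )


# Fixed first-match order of the leukocyte decision tree. Each rule is a list
# of (marker, wanted_positive) requirements on transformed positivity calls.
LINEAGE_TREE: list[tuple[str, list[tuple[str, bool]]]] = [
    ("eosinophil", [("CD66b", True), ("CD294", True)]),
    ("neutrophil", [("CD66b", True), ("CD16", True)]),
    ("basophil", [("CD294", True), ("CD66b", False), ("HLA-DR", False)]),
    ("B", [("CD19", True), ("CD3", False)]),
    ("gdT", [("CD3", True), ("TCRgd", True)]),
    ("MAIT_iNKT", [("CD3", True), ("Va7.2", True)]),
    ("CD4T", [("CD3", True), ("CD4", True), ("CD8", False)]),
    ("CD8T", [("CD3", True), ("CD8", True), ("CD4", False)]),
    ("NK", [("CD56", True), ("CD3", False)]),
    ("monocyte:CD14", [("CD14", True), ("CD3", False), ("CD19", False), ("CD66b", False)]),
    ("monocyte:CD33", [("CD33", True), ("CD3", False), ("CD19", False), ("CD66b", False)]),
    ("DC", [("HLA-DR", True), ("CD3", False), ("CD19", False), ("CD14", False),
            ("CD56", False), ("CD66b", False)]),
    ("ILC", [("CD127", True), ("CD3", False), ("CD19", False), ("CD14", False),
             ("CD56", False), ("CD66b", False), ("HLA-DR", False)]),
]


def gate_leukocyte_subsets(
    table: EventTable, config: GatingConfig | None = None, labels: CellLabel | None = None
) -> CellLabel:
    """Assign each intact CD45+ singlet to one of the 12 subsets.

    First-match in the documented :data:`LINEAGE_TREE` order; events matching
    no rule stay ``unassigned``. The order is part of the config hash.
    """
    config = config or GatingConfig()
    labels = labels or gate_intact_singlets(table, config)
    tr = _Transformed(table, config)
    needed = {"CD45"} | {m for _, reqs in LINEAGE_TREE for m, _ in reqs}
    missing = [m for m in sorted(needed) if m not in table.panel.markers]
    if missing:
        raise PanelError(f"leukocyte tree requires markers missing from the panel: {missing}")

    cd45 = tr.positive("CD45")
    labels.is_cd45 = cd45
    candidate = labels.is_intact & cd45
    unlabeled = candidate.copy()
    lineage = labels.lineage
    for name, reqs in LINEAGE_TREE:
        mask = unlabeled.copy()
        for marker, wanted in reqs:
            mask &= tr.positive(marker) if wanted else ~tr.positive(marker)
        lineage[mask] = name.split(":")[0]
        unlabeled &= ~mask
    return labels


_FIBROBLAST_FLAGS = ("CDH11", "CD34", "CD90", "Notch3", "HLA-DR") + CHEMOKINE_RECEPTORS
_FIBROCYTE_FLAGS = ("CDH11", "PDPN", "CD90", "Notch3") + CHEMOKINE_RECEPTORS


def _rare_gate(
    table: EventTable,
    config: GatingConfig,
    labels: CellLabel | None,
    cd45_positive: bool,
    required: tuple[str, ...],
    flag_markers: tuple[str, ...],
) -> pd.DataFrame:
    labels = labels or gate_intact_singlets(table, config)
    tr = _Transformed(table, config)
    mask = labels.is_intact.copy()
    cd45 = tr.positive("CD45")
    mask &= cd45 if cd45_positive else ~cd45
    for m in LINEAGE_EXCLUSION:
        mask &= ~tr.positive(m)
    for m in required:
        mask &= tr.positive(m)
    idx = np.flatnonzero(mask)
    rec = {"event_index": idx}
    for m in flag_markers:
        rec[m] = tr.positive(m)[idx]
    return pd.DataFrame(rec)


def gate_fibroblasts(
    table: EventTable, config: GatingConfig | None = None, labels: CellLabel | None = None
) -> pd.DataFrame:
    """Circulating fibroblasts: PDPN+CD45- lineage-negative intact singlets.

    Returns one record per gated cell with Boolean flags for CDH11, CD34,
    CD90, Notch3, HLA-DR and the five chemokine receptors.
    """
    config = config or GatingConfig()
    return _rare_gate(table, config, labels, cd45_positive=False,
                      required=("PDPN",), flag_markers=_FIBROBLAST_FLAGS)


def gate_fibrocytes(
    table: EventTable, config: GatingConfig | None = None, labels: CellLabel | None = None
) -> pd.DataFrame:
    """Fibrocytes: CD34+HLA-DR+CD45+ lineage-negative intact singlets.

    Disjoint from the fibroblast gate by the CD45 requirement.
    """
    config = config or GatingConfig()
    return _rare_gate(table, config, labels, cd45_positive=True,
                      required=("CD34", "HLA-DR"), flag_markers=_FIBROCYTE_FLAGS)


def coexpression_counts(
    labels: CellLabel, table: EventTable, config: GatingConfig | None = None
) -> tuple[pd.DataFrame, float]:
    """CDH11+CD90+ counts per leukocyte subset, with nested sub-counts.

    Returns the per-subset table (events, double-positives, Notch3+ and
    per-receptor sub-counts of the double-positives) and the overall
    double-positive fraction of intact CD45+ events.
    """
    config = config or GatingConfig()
    tr = _Transformed(table, config)
    dp = tr.positive("CDH11") & tr.positive("CD90")
    notch3 = tr.positive("Notch3")
    receptors = {r: tr.positive(r) for r in CHEMOKINE_RECEPTORS}

    from .design import LEUKOCYTE_SUBSETS

    rows = []
    for subset in LEUKOCYTE_SUBSETS:
        sel = labels.lineage == subset
        sub_dp = sel & dp
        row = {
            "subset": subset,
            "n_events": int(sel.sum()),
            "cdh11_cd90": int(sub_dp.sum()),
            "cdh11_cd90_notch3": int((sub_dp & notch3).sum()),
        }
        for r, pos in receptors.items():
            row[f"cdh11_cd90_{r}"] = int((sub_dp & pos).sum())
        rows.append(row)
    cd45_events = labels.is_intact & labels.is_cd45
    n_cd45 = int(cd45_events.sum())
    frac = float((cd45_events & dp).sum() / n_cd45) if n_cd45 else float("nan")
    return pd.DataFrame(rows), frac
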