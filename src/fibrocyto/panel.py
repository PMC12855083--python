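"""Antibody panel model for the whole-blood CyTOF assay.

The panel couples each acquisition channel (metal isotope) to a marker name
and a functional role. Roles drive everything downstream: the DNA and
event-length channels feed the singlet gate, the bead channel feeds drift
normalization, lineage markers feed the leukocyte tree, and the mesenchymal
and chemokine sets define the rare-cell phenotype space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MESENCHYMAL_MARKERS = ("CDH11", "PDPN", "CD90", "CD34", "Notch3")
CHEMOKINE_RECEPTORS = ("CCR4", "CCR6", "CCR7", "CXCR3", "CXCR5")

#: Lineage-exclusion panel used for both rare-cell gates.
LINEAGE_EXCLUSION = ("CD3", "CD19", "CD4", "CD8", "CD56", "CD66b", "CD294")

ROLES = ("lineage", "mesenchymal", "chemokine", "dna", "bead", "event_length", "other")


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class Channel:
    metal: str
    marker: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise PanelError(f"unknown channel role {self.role!r} for {self.marker}")


@dataclass
class Panel:
    """Ordered list of channels with unique marker names.

    Invariants: two DNA channels (iridium intercalator), exactly one
    event-length channel, unique marker names.
    """

    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [c.marker for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate marker names in panel: {dupes}")
        if sum(c.role == "dna" for c in self.channels) != 2:
            raise PanelError("panel must declare exactly two DNA channels")
        if sum(c.role == "event_length" for c in self.channels) != 1:
            raise PanelError("panel must declare exactly one event_length channel")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    @property
    def metals(self) -> list[str]:
        return [c.metal for c in self.channels]

    def index(self, marker: str) -> int:
        for i, c in enumerate(self.channels):
            if c.marker == marker:
                return i
        raise PanelError(f"marker {marker!r} not in panel")

    def indices(self, markers) -> list[int]:
        return [self.index(m) for m in markers]

    def by_role(self, role: str) -> list[str]:
        return [c.marker for c in self.channels if c.role == role]

    @property
    def dna_markers(self) -> list[str]:
        return self.by_role("dna")

    @property
    def bead_markers(self) -> list[str]:
        return self.by_role("bead")

    @property
    def event_length_marker(self) -> str:
        return self.by_role("event_length")[0]


# Role lookup used when reconstructing a Panel from an FCS file whose TEXT
# segment carries only metal/marker names.
_ROLE_BY_MARKER = {
    "DNA1": "dna",
    "DNA2": "dna",
    "Event_length": "event_length",
    "Bead": "bead",
    **{m: "mesenchymal" for m in MESENCHYMAL_MARKERS},
    **{m: "chemokine" for m in CHEMOKINE_RECEPTORS},
}

_LINEAGE_PANEL = (
    ("Y89", "CD45"),
    ("Yb172", "CD66b"),
    ("Nd148", "CD16"),
    ("Er166", "CD294"),
    ("Yb173", "HLA-DR"),
    ("Er168", "CD14"),
    ("Gd160", "CD33"),
    ("Dy163", "CD56"),
    ("Er170", "CD3"),
    ("Nd144", "CD19"),
    ("Nd145", "CD4"),
    ("Nd146", "CD8"),
    ("Dy164", "TCRgd"),
    ("Eu153", "Va7.2"),
    ("Yb176", "CD127"),
)

_MESENCHYMAL_PANEL = (
    ("Nd142", "CDH11"),
    ("Nd143", "PDPN"),
    ("Sm149", "CD90"),
    ("Nd150", "CD34"),
    ("Eu151", "Notch3"),
)

_CHEMOKINE_PANEL = (
    ("Sm152", "CCR4"),
    ("Pr141", "CCR6"),
    ("Er167", "CCR7"),
    ("Gd156", "CXCR3"),
    ("Gd158", "CXCR5"),
)


def infer_role(marker: str) -> str:
    if marker in _ROLE_BY_MARKER:
        return _ROLE_BY_MARKER[marker]
    if marker in {m for _, m in _LINEAGE_PANEL}:
        return "lineage"
    return "other"


def default_panel() -> Panel:
    """The 29-channel panel the simulator and gates assume.

    A 30-marker commercial immune-profiling backbone reduced to the markers
    the analysis actually consumes, plus the five mesenchymal markers, five
    chemokine receptors, DNA intercalator, calibration-bead and event-length
    channels.
    """
    channels = [
        Channel("Ce140", "Bead", "bead"),
        Channel("Ir191", "DNA1", "dna"),
        Channel("Ir193", "DNA2", "dna"),
        Channel("Time", "Event_length", "event_length"),
    ]
    channels += [Channel(metal, marker, "lineage") for metal, marker in _LINEAGE_PANEL]
    channels += [Channel(metal, marker, "mesenchymal") for metal, marker in _MESENCHYMAL_PANEL]
    channels += [Channel(metal, marker, "chemokine") for metal, marker in _CHEMOKINE_PANEL]
    return Panel(channels)
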