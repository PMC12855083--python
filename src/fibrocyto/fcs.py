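"""FCS 3.1 event-file I/O and bead-based signal normalization.

Files are written in the common CyTOF export dialect: a single list-mode
float32 data segment, ``$PnN`` carrying the metal tag and ``$PnS`` the
marker name. Acquisition metadata (stained volume, acquisition fraction,
sample id) travels in custom TEXT keywords so a table survives a round trip.

Bead normalization corrects slow detector-sensitivity drift using the
metal-embedded calibration beads acquired alongside cells: events are cut
into fixed-size acquisition windows, the bead-channel median is computed per
window, and every window is rescaled so bead medians are constant across the
run. The correction is deliberately piecewise-constant from *unsmoothed*
window medians with the reference set to the mean of window medians — that
exact combination makes the operation idempotent to float precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel import Channel, Panel, PanelError, infer_role

log = logging.getLogger(__name__)


class FCSFormatError(ValueError):
    """Malformed FCS header or TEXT segment; message names the keyword."""


@dataclass
class EventTable:
    """Per-sample events x channels matrix of raw ion dual counts."""

    sample_id: str
    data: np.ndarray  # (n_events, n_channels) nonnegative float32
    panel: Panel
    stained_volume_ml: float = 0.27
    acquisition_fraction: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("event data must be 2-D (events x channels)")
        if self.data.shape[1] != len(self.panel):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but panel has {len(self.panel)} channels"
            )
        if self.stained_volume_ml <= 0 or self.acquisition_fraction <= 0:
            raise ValueError("stained_volume_ml and acquisition_fraction must be > 0")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def effective_volume_ml(self) -> float:
        return self.stained_volume_ml * self.acquisition_fraction

    def marker(self, name: str) -> np.ndarray:
        """Raw intensity column for one marker."""
        return self.data[:, self.panel.index(name)]

    def validate(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError("event table contains NaN intensities")
        if (self.data < 0).any():
            raise ValueError("event table contains negative intensities")

    def subset(self, mask: np.ndarray) -> "EventTable":
        return replace(self, data=self.data[mask])


# ---------------------------------------------------------------------------
# FCS 3.1 read / write
# ---------------------------------------------------------------------------

_DELIM = "/"
_CUSTOM_KEYS = ("SAMPLE_ID", "STAINED_VOLUME_ML", "ACQUISITION_FRACTION")


def _text_segment(table: EventTable, data_begin: int, data_end: int) -> bytes:
    n_ev, n_ch = table.data.shape
    kv: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": f"{data_begin:>12d}",
        "$ENDDATA": f"{data_end:>12d}",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_ch),
        "$TOT": str(n_ev),
        "SAMPLE_ID": table.sample_id,
        "STAINED_VOLUME_ML": repr(float(table.stained_volume_ml)),
        "ACQUISITION_FRACTION": repr(float(table.acquisition_fraction)),
    }
    ranges = table.data.max(axis=0, initial=0.0)
    for i, ch in enumerate(table.panel.channels, start=1):
        kv[f"$P{i}N"] = ch.metal
        kv[f"$P{i}S"] = ch.marker
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(np.ceil(ranges[i - 1])) + 1)
    parts = [_DELIM]
    for k, v in kv.items():
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(table: EventTable, path) -> None:
    """Write one sample as an FCS 3.1 file (float32, list mode)."""
    table.validate()
    header_len = 58
    # Two-pass: offsets are written with fixed-width placeholders, so the
    # TEXT length is independent of their value.
    text = _text_segment(table, 0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + table.data.size * 4 - 1
    text = _text_segment(table, data_begin, data_end)
    assert text_begin + len(text) - 1 == text_end

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if data_begin <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(np.ascontiguousarray(table.data, dtype="<f4").tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    txt = raw.decode("ascii", errors="replace")
    delim = txt[0]
    fields = txt[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FCSFormatError("TEXT segment has an odd number of delimited fields")
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def _require(kv: dict[str, str], key: str) -> str:
    if key not in kv:
        raise FCSFormatError(f"missing required keyword {key}")
    return kv[key]


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Marker names come from ``$PnS`` when present, falling back to ``$PnN``
    with a logged warning; roles are inferred from the marker names. The
    reconstructed panel must satisfy the standard invariants (two DNA
    channels, one event-length channel).
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58 or not header[:6] in (b"FCS3.0", b"FCS3.1"):
            raise FCSFormatError("not an FCS 3.0/3.1 file (bad version string)")
        try:
            text_begin = int(header[10:18])
            text_end = int(header[18:26])
        except ValueError as exc:
            raise FCSFormatError("unreadable TEXT offsets in header") from exc
        fh.seek(text_begin)
        kv = _parse_text(fh.read(text_end - text_begin + 1))

        if _require(kv, "$DATATYPE") != "F":
            raise FCSFormatError("$DATATYPE: only float (F) data supported")
        if _require(kv, "$MODE") != "L":
            raise FCSFormatError("$MODE: only list mode (L) supported")
        byteord = _require(kv, "$BYTEORD")
        if byteord == "1,2,3,4":
            dtype = "<f4"
        elif byteord == "4,3,2,1":
            dtype = ">f4"
        else:
            raise FCSFormatError(f"$BYTEORD: unsupported byte order {byteord!r}")
        n_par = int(_require(kv, "$PAR"))
        n_tot = int(_require(kv, "$TOT"))

        data_begin = int(kv.get("$BEGINDATA", "0")) or int(header[26:34])
        fh.seek(data_begin)
        buf = fh.read(n_tot * n_par * 4)

    if len(buf) < n_tot * n_par * 4:
        raise FCSFormatError("$TOT: data segment shorter than $TOT*$PAR events")
    data = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par).astype(np.float32)

    channels = []
    for i in range(1, n_par + 1):
        metal = _require(kv, f"$P{i}N")
        marker = kv.get(f"$P{i}S")
        if marker is None:
            log.warning("channel %d has no $PnS; falling back to $PnN=%s", i, metal)
            marker = metal
        channels.append(Channel(metal, marker, infer_role(marker)))
    panel = Panel(channels)  # raises PanelError on missing DNA etc.

    return EventTable(
        sample_id=kv.get("SAMPLE_ID", "unknown"),
        data=data,
        panel=panel,
        stained_volume_ml=float(kv.get("STAINED_VOLUME_ML", 0.27)),
        acquisition_fraction=float(kv.get("ACQUISITION_FRACTION", 1.0)),
    )


# ---------------------------------------------------------------------------
# Bead normalization
# ---------------------------------------------------------------------------


class BeadNormalizationError(RuntimeError):
    """Insufficient calibration beads to estimate drift."""


@dataclass
class NormalizationReport:
    """Per-window scale factors and bead diagnostics."""

    factors: pd.DataFrame  # columns: window, start, end, n_beads, bead_median, scale
    n_beads: int
    drift_before: float
    drift_after: float


def identify_beads(table: EventTable, cofactor: float = 5.0, threshold: float = 1.5) -> np.ndarray:
    """Boolean mask of calibration-bead events: bead channel high, DNA low."""
    bead_markers = table.panel.bead_markers
    if not bead_markers:
        raise PanelError("panel declares no bead channel")
    tr = lambda x: np.arcsinh(x / cofactor)
    bead_hi = np.ones(table.n_events, dtype=bool)
    for m in bead_markers:
        bead_hi &= tr(table.marker(m)) > threshold
    dna_lo = np.ones(table.n_events, dtype=bool)
    for m in table.panel.dna_markers:
        dna_lo &= tr(table.marker(m)) < threshold
    return bead_hi & dna_lo


def _fitted_drift(window_medians: np.ndarray) -> float:
    """|fitted linear change across the run| / mean, from per-window medians."""
    m = window_medians[np.isfinite(window_medians)]
    if len(m) < 2 or m.mean() == 0:
        return 0.0
    x = np.arange(len(m))
    slope = np.polyfit(x, m, 1)[0]
    return abs(slope * (len(m) - 1)) / m.mean()


def bead_normalize(
    table: EventTable,
    window_events: int = 2000,
    min_beads: int = 50,
    keep_beads: bool = False,
) -> tuple[EventTable, NormalizationReport]:
    """Rescale intensities per acquisition window so bead medians are flat.

    Events are assumed acquired in row order. All channels except event
    length are rescaled (sensitivity drift is a property of the detector,
    not of a marker). Bead events are removed unless ``keep_beads``.
    """
    is_bead = identify_beads(table)
    n_beads = int(is_bead.sum())
    if n_beads < min_beads:
        raise BeadNormalizationError(
            f"only {n_beads} bead events found (need >= {min_beads}) — cannot calibrate"
        )

    bead_cols = table.panel.indices(table.panel.bead_markers)
    n = table.n_events
    n_windows = max(1, n // window_events)
    edges = np.linspace(0, n, n_windows + 1).astype(int)
    window_of = np.clip(np.searchsorted(edges, np.arange(n), side="right") - 1, 0, n_windows - 1)

    medians = np.full(n_windows, np.nan)
    counts = np.zeros(n_windows, dtype=int)
    bead_signal = table.data[:, bead_cols].mean(axis=1)
    for w in range(n_windows):
        sel = is_bead & (window_of == w)
        counts[w] = sel.sum()
        if counts[w]:
            medians[w] = np.median(bead_signal[sel])
    if np.isnan(medians).any():  # windows without beads: nearest/linear fill
        idx = np.arange(n_windows)
        ok = ~np.isnan(medians)
        medians = np.interp(idx, idx[ok], medians[ok])

    reference = medians.mean()
    scale = reference / medians
    drift_before = _fitted_drift(medians)

    out = table.data.copy()
    ev_len_col = table.panel.index(table.panel.event_length_marker)
    chan = [i for i in range(len(table.panel)) if i != ev_len_col]
    out[:, chan] *= scale[window_of][:, None].astype(np.float32)

    # post-correction bead medians per window, for the report
    post_medians = np.full(n_windows, np.nan)
    post_signal = out[:, bead_cols].mean(axis=1)
    for w in range(n_windows):
        sel = is_bead & (window_of == w)
        if sel.sum():
            post_medians[w] = np.median(post_signal[sel])
    drift_after = _fitted_drift(post_medians)

    report = NormalizationReport(
        factors=pd.DataFrame(
            {
                "window": np.arange(n_windows),
                "start": edges[:-1],
                "end": edges[1:],
                "n_beads": counts,
                "bead_median": medians,
                "scale": scale,
            }
        ),
        n_beads=n_beads,
        drift_before=drift_before,
        drift_after=drift_after,
    )
    result = replace(table, data=out if keep_beads else out[~is_bead])
    return result, report
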