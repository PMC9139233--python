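"""Reading and writing Flow Cytometry Standard (FCS) files and label sidecars.

Implements the subset of FCS 3.0/3.1 this pipeline needs: single-dataset,
list-mode files. Written files are FCS 3.1, float ($DATATYPE F), little-endian,
with no $SPILLOVER keyword — the classifier consumes raw, uncompensated
intensities, so no compensation matrix is ever attached.

Ground-truth / predicted per-event class labels travel in a separate CSV
sidecar (``event_index,label``), order-aligned with the FCS events, rather
than being smuggled into FCS keywords; this keeps the FCS files readable by
any standard tool.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .ontology import (
    CHANNEL_NAMES,
    CLASSES,
    Channel,
    N_CHANNELS,
    PANEL,
)

__all__ = [
    "EventMatrix",
    "CaseSample",
    "FCSFormatError",
    "PanelMismatchError",
    "LabelAlignmentError",
    "read_fcs",
    "write_fcs",
    "read_labels",
    "write_labels",
    "write_population_files",
    "read_population_files",
]


class FCSFormatError(ValueError):
    """File is not a parseable FCS 3.0/3.1 dataset."""


class PanelMismatchError(ValueError):
    """File's parameter set does not match the expected 13-channel panel."""


class LabelAlignmentError(ValueError):
    """Label sidecar does not align with its companion event matrix."""


@dataclass(eq=False)
class EventMatrix:
    """N x 13 table of per-event scatter/fluorescence intensities.

    ``values`` is float32, one row per event in acquisition order; ``channels``
    gives the ordered parameter descriptions.
    """

    values: np.ndarray
    channels: tuple[Channel, ...] = PANEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.channels))
        if self.values.shape[1] != len(self.channels):
            raise PanelMismatchError(
                f"event matrix has {self.values.shape[1]} columns, "
                f"panel declares {len(self.channels)} channels"
            )
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("event intensities must be finite")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    def __len__(self) -> int:
        return self.n_events


@dataclass(eq=False)
class CaseSample:
    """One specimen: events, optional per-event ground truth, metadata."""

    events: EventMatrix
    truth: np.ndarray | None = None
    case_id: str = ""
    specimen: Literal["peripheral_blood", "bone_marrow"] = "peripheral_blood"
    true_cll_fraction: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=object).astype(str)
            if len(self.truth) != self.events.n_events:
                raise LabelAlignmentError(
                    f"truth has {len(self.truth)} labels for "
                    f"{self.events.n_events} events"
                )
            bad = set(self.truth) - set(CLASSES)
            if bad:
                raise ValueError(
                    f"unknown class labels {sorted(bad)}; allowed: {list(CLASSES)}"
                )

    @property
    def n_events(self) -> int:
        return self.events.n_events


# --------------------------------------------------------------------------
# FCS reading

_HEADER_LEN = 58


def _parse_header(raw: bytes) -> tuple[str, list[int]]:
    if len(raw) < _HEADER_LEN:
        raise FCSFormatError("file too short to contain an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FCSFormatError(f"not an FCS file (magic {version!r})")
    offsets = []
    for i in range(6):
        fldstart = 10 + 8 * i
        fld = raw[fldstart : fldstart + 8].decode("ascii", errors="replace").strip()
        offsets.append(int(fld) if fld else 0)
    return version, offsets


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = [p.decode("utf-8", errors="replace") for p in body.split(delim)]
    # A doubled delimiter is an escaped literal delimiter inside a value,
    # which surfaces here as an empty token between two fragments (keyword
    # values themselves may never be empty per the standard).
    merged: list[str] = []
    i = 0
    d = delim.decode()
    while i < len(parts):
        tok = parts[i]
        i += 1
        while i + 1 < len(parts) and parts[i] == "":
            tok += d + parts[i + 1]
            i += 2
        merged.append(tok)
    if len(merged) % 2 == 1:
        merged = merged[:-1]
    kw = {}
    for k, v in zip(merged[0::2], merged[1::2]):
        kw[k.strip().upper()] = v
    if not kw:
        raise FCSFormatError("TEXT segment contains no keywords")
    return kw


def read_fcs(
    path: str | os.PathLike,
    *,
    require_panel: bool = True,
) -> EventMatrix:
    """Read a list-mode FCS 3.0/3.1 file into an :class:`EventMatrix`.

    Events are returned in acquisition order. Channel names are taken from
    $PnS (stain) with $PnN (short name) as fallback. With ``require_panel``
    (the default) the file must carry exactly the 13-parameter CLL MRD panel;
    set it to False to read arbitrary list-mode files.
    """
    raw = Path(path).read_bytes()
    if not raw:
        raise FCSFormatError(f"{path}: empty file")
    version, offs = _parse_header(raw)
    if version[3:] not in ("3.0", "3.1"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")
    text_begin, text_end = offs[0], offs[1]
    if not (0 < text_begin < text_end < len(raw)):
        raise FCSFormatError("invalid TEXT segment offsets in header")
    kw = _parse_text_segment(raw[text_begin : text_end + 1])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        mode = kw["$MODE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FCSFormatError(f"missing required keyword {exc.args[0]}") from None
    if mode != "L":
        raise FCSFormatError(f"only list mode ($MODE L) supported, got {mode!r}")
    if int(kw.get("$NEXTDATA", "0")) != 0:
        raise FCSFormatError("multi-dataset FCS files are not supported")

    data_begin = offs[2] or int(kw.get("$BEGINDATA", "0"))
    data_end = offs[3] or int(kw.get("$ENDDATA", "0"))
    if n_tot > 0 and not (0 < data_begin <= data_end + 1 <= len(raw) + 1):
        raise FCSFormatError("invalid DATA segment offsets")

    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FCSFormatError(f"unsupported $BYTEORD {byteord!r}")

    bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FCSFormatError("mixed per-parameter bit widths are not supported")
    nbits = bits.pop()
    if datatype == "F":
        if nbits != 32:
            raise FCSFormatError("$DATATYPE F requires $PnB 32")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        if nbits not in (16, 32):
            raise FCSFormatError(f"unsupported integer width {nbits}")
        dtype = np.dtype(endian + ("u2" if nbits == 16 else "u4"))
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")

    n_values = n_tot * n_par
    buf = raw[data_begin : data_begin + n_values * dtype.itemsize]
    if len(buf) < n_values * dtype.itemsize:
        raise FCSFormatError("DATA segment shorter than $TOT * $PAR values")
    values = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par)

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        kind = "scatter" if name.split("-")[0] in ("FSC", "SSC") else "fluorescence"
        channels.append(Channel(name, kind))

    if require_panel:
        got = {c.name for c in channels}
        want = set(CHANNEL_NAMES)
        if got != want:
            raise PanelMismatchError(
                f"file panel {sorted(got)} does not match expected CLL MRD panel "
                f"{sorted(want)}"
            )
        # Panels are matched by channel name, not position.
        order = [
            next(i for i, c in enumerate(channels) if c.name == n)
            for n in CHANNEL_NAMES
        ]
        values = values[:, order]
        channels = [channels[i] for i in order]

    values = np.ascontiguousarray(values, dtype=np.float32)
    return EventMatrix(values=values, channels=tuple(channels))


# --------------------------------------------------------------------------
# FCS writing


def _kw_bytes(kw: dict[str, str], delim: bytes = b"/") -> bytes:
    out = [delim]
    d = delim.decode()
    for k, v in kw.items():
        out.append(str(k).replace(d, d + d).encode())
        out.append(delim)
        out.append(str(v).replace(d, d + d).encode())
        out.append(delim)
    return b"".join(out)


def write_fcs(events: EventMatrix, path: str | os.PathLike) -> None:
    """Write an :class:`EventMatrix` as a single-dataset FCS 3.1 file.

    Float32 list mode, little-endian, $TOT/$PAR consistent with the data.
    No $SPILLOVER keyword is emitted (data are uncompensated by design).
    """
    values = np.ascontiguousarray(events.values, dtype="<f4")
    n_tot, n_par = values.shape

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # Fixed-width placeholders so TEXT length is offset-independent.
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, ch in enumerate(events.channels, start=1):
        kw[f"$P{i}N"] = ch.name
        kw[f"$P{i}S"] = ch.name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(values[:, i - 1].max()) if n_tot else 0.0
        kw[f"$P{i}R"] = str(max(1024, int(np.ceil(rng)) + 1))

    text = _kw_bytes(kw)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.nbytes - 1 if n_tot else 0

    kw["$BEGINDATA"] = "%012d" % data_begin
    kw["$ENDDATA"] = "%012d" % (data_end if n_tot else 0)
    text = _kw_bytes(kw)
    assert text_end == text_begin + len(text) - 1

    def fld(x: int) -> bytes:
        s = str(x)
        return (b" " * (8 - len(s)) + s.encode()) if len(s) <= 8 else b"       0"

    header = (
        b"FCS3.1    "
        + fld(text_begin)
        + fld(text_end)
        + fld(data_begin if values.nbytes else 0)
        + fld(data_end)
        + fld(0)
        + fld(0)
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


# --------------------------------------------------------------------------
# Label sidecars


def write_labels(labels: Sequence[str] | np.ndarray, path: str | os.PathLike) -> None:
    """Write per-event class labels as a CSV sidecar (``event_index,label``)."""
    labels = np.asarray(labels, dtype=object).astype(str)
    bad = set(labels) - set(CLASSES)
    if bad:
        raise ValueError(
            f"unknown class labels {sorted(bad)}; allowed: {list(CLASSES)}"
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_index", "label"])
        for i, lab in enumerate(labels):
            w.writerow([i, lab])


def read_labels(
    path: str | os.PathLike, *, expect_n: int | None = None
) -> np.ndarray:
    """Read a label sidecar; optionally check alignment with a companion FCS."""
    labels: list[str] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header is None:
            labels = []
        else:
            if [h.strip().lower() for h in header] != ["event_index", "label"]:
                # Headerless single-column variant: one label per line.
                if len(header) == 1:
                    labels.append(header[0].strip())
                else:
                    raise LabelAlignmentError(
                        f"{path}: expected header 'event_index,label'"
                    )
            for row in r:
                if not row:
                    continue
                labels.append(row[-1].strip())
    arr = np.asarray(labels, dtype=object).astype(str) if labels else np.empty(0, dtype="<U32")
    bad = set(arr) - set(CLASSES)
    if bad:
        raise ValueError(
            f"unknown class labels {sorted(bad)}; allowed: {list(CLASSES)}"
        )
    if expect_n is not None and len(arr) != expect_n:
        raise LabelAlignmentError(
            f"{path}: {len(arr)} labels for {expect_n} events"
        )
    return arr


# --------------------------------------------------------------------------
# Per-population export (expert-gated populations as individual FCS files)


def write_population_files(case: CaseSample, out_dir: str | os.PathLike) -> list[Path]:
    """Split a labeled case into one FCS file per non-empty class.

    Mirrors the laboratory convention of providing each gated population as
    its own FCS file. Filenames encode case id and class name. Returns the
    written paths (ontology order).
    """
    if case.truth is None:
        raise ValueError("case has no ground-truth labels to split on")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for cls in CLASSES:
        mask = case.truth == cls
        if not mask.any():
            continue
        sub = EventMatrix(case.events.values[mask], case.events.channels)
        p = out_dir / f"{case.case_id or 'case'}__{cls}.fcs"
        write_fcs(sub, p)
        paths.append(p)
    return paths


def read_population_files(paths: Sequence[str | os.PathLike]) -> CaseSample:
    """Pool per-population FCS files back into a single labeled case.

    The class of each file is parsed from the ``<case>__<class>.fcs`` name.
    """
    values = []
    labels = []
    case_id = ""
    channels = PANEL
    for p in paths:
        p = Path(p)
        stem = p.stem
        if "__" not in stem:
            raise ValueError(f"{p}: filename does not encode a class name")
        case_id, cls = stem.rsplit("__", 1)
        if cls not in CLASSES:
            raise ValueError(f"{p}: unknown class {cls!r}")
        m = read_fcs(p)
        channels = m.channels
        values.append(m.values)
        labels.extend([cls] * m.n_events)
    vals = np.vstack(values) if values else np.empty((0, N_CHANNELS), np.float32)
    return CaseSample(
        events=EventMatrix(vals, channels),
        truth=np.asarray(labels, dtype=object).astype(str) if labels else np.empty(0, "<U32"),
        case_id=case_id,
    )
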