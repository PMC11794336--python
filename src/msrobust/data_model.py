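"""Core data types, montage geometry and EEG file I/O.

Everything downstream operates on three containers: :class:`Montage`
(electrode labels and positions on the scalp sphere), :class:`Recording`
(a channels x samples matrix in microvolts with eyes-open/eyes-closed block
annotations) and :class:`Topography` (one scalp map).

Conventions
-----------
* Head-centred RAS coordinates, z toward the vertex, positions in mm on a
  sphere of radius 85 mm (the outermost shell of the spherical head model).
* Amplitudes are microvolts everywhere; unit conversion happens only at the
  I/O boundary (EDF stores its own physical scaling, mne returns Volts).
* Block annotations are half-open sample intervals tagged "EO" or "EC".
"""

from __future__ import annotations

import datetime
import io
import os
from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Sequence, Tuple

import numpy as np

SCALP_RADIUS_MM = 85.0

__all__ = [
    "SCALP_RADIUS_MM",
    "Montage",
    "Block",
    "Recording",
    "Topography",
    "FormatError",
    "MontageError",
    "standard_1010_montage",
    "read_recording",
    "write_recording",
]


class FormatError(ValueError):
    """File does not parse under the named standard."""


class MontageError(ValueError):
    """Channel labels or positions are inconsistent with the montage."""


# --------------------------------------------------------------------------
# montage
# --------------------------------------------------------------------------

#: 62-channel 10-10 layout of the ActiCAP-style resting-state cap.
LABELS_62 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT7", "FC3", "FC4", "FT8", "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8", "FT9", "FT10",
]

#: 19-channel 10-20 subset, the desk-scale default for simulations.
LABELS_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

#: 12-channel minimal subset for fast unit tests.
LABELS_12 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4",
    "T7", "T8", "P3", "P4", "O1", "O2",
]

_SUPPORTED = {62: LABELS_62, 19: LABELS_19, 12: LABELS_12}


@dataclass(frozen=True)
class Montage:
    """Electrode labels and 3D positions on the scalp sphere (mm)."""

    labels: Tuple[str, ...]
    positions: np.ndarray  # (n, 3) float, |row| == SCALP_RADIUS_MM

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(set(self.labels)):
            raise MontageError("duplicate channel labels")
        if pos.shape != (len(self.labels), 3):
            raise MontageError("positions shape does not match labels")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, SCALP_RADIUS_MM, atol=1e-6):
            raise MontageError("positions must lie on the scalp sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])

    def permuted(self, order: Sequence[int]) -> "Montage":
        order = list(order)
        return Montage(tuple(self.labels[i] for i in order), self.positions[order])


_MONTAGE_CACHE: dict = {}


def _template_positions() -> dict:
    """Idealised 10-10 electrode directions from the mne standard montage,
    re-centred on the best-fit sphere and rotated so Cz is the +z pole and
    Fpz defines the +y (anterior) direction."""
    if "pos" in _MONTAGE_CACHE:
        return _MONTAGE_CACHE["pos"]
    import mne

    std = mne.channels.make_standard_montage("colin27_1005")
    ch_pos = std.get_positions()["ch_pos"]
    wanted = set(LABELS_62) | {"Fpz"}
    pts = {k: np.asarray(v, float) for k, v in ch_pos.items() if k in wanted}
    arr = np.array(list(pts.values()))

    # least-squares sphere fit: |p - c|^2 = r^2
    A = np.c_[2 * arr, np.ones(len(arr))]
    b = (arr ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]

    dirs = {k: (v - centre) / np.linalg.norm(v - centre) for k, v in pts.items()}
    z = dirs["Cz"]
    y = dirs["Fpz"] - np.dot(dirs["Fpz"], z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    R = np.array([x, y, z])  # rows are the new axes
    out = {k: R @ v for k, v in dirs.items()}
    _MONTAGE_CACHE["pos"] = out
    return out


def standard_1010_montage(n_channels: int = 62) -> Montage:
    """Deterministic 10-10 montage on the 85 mm scalp sphere.

    Supported sizes: 62 (full cap), 19 (10-20 subset), 12 (minimal).
    """
    if n_channels not in _SUPPORTED:
        raise MontageError(
            f"unsupported channel count {n_channels}; supported: {sorted(_SUPPORTED)}"
        )
    key = ("montage", n_channels)
    if key not in _MONTAGE_CACHE:
        dirs = _template_positions()
        labels = _SUPPORTED[n_channels]
        pos = np.array([dirs[l] for l in labels]) * SCALP_RADIUS_MM
        # renormalise exactly onto the sphere
        pos *= SCALP_RADIUS_MM / np.linalg.norm(pos, axis=1, keepdims=True)
        _MONTAGE_CACHE[key] = Montage(tuple(labels), pos)
    return _MONTAGE_CACHE[key]


# --------------------------------------------------------------------------
# recording / topography
# --------------------------------------------------------------------------


class Block(NamedTuple):
    """Half-open sample interval [start, stop) in one condition."""

    start: int
    stop: int
    condition: str  # "EO" or "EC"


@dataclass
class Recording:
    """Multichannel EEG: channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    blocks: List[Block] = field(default_factory=list)
    reference: str = "common"  # or "average"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise MontageError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        self.blocks = [Block(int(b[0]), int(b[1]), str(b[2])) for b in self.blocks]
        last = 0
        for b in sorted(self.blocks, key=lambda b: b.start):
            if b.start < last or b.stop <= b.start or b.stop > self.n_samples:
                raise ValueError(f"invalid or overlapping block {b}")
            if b.condition not in ("EO", "EC"):
                raise ValueError(f"unknown condition {b.condition!r}")
            last = b.stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "blocks" not in changes:
            out.blocks = list(self.blocks)
        return out

    def block_data(self, condition: str | None = None):
        """Yield (block, data view) pairs, optionally filtered by condition."""
        for b in self.blocks:
            if condition is None or b.condition == condition:
                yield b, self.data[:, b.start : b.stop]


@dataclass
class Topography:
    """One scalp map: a value per channel, microvolts."""

    values: np.ndarray
    montage: Montage
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.montage.n_channels:
            raise MontageError("topography length does not match montage")
        if not np.all(np.isfinite(v)):
            raise ValueError("topography values must be finite")
        self.values = v
        if self.normalized:
            if abs(v.mean()) > 1e-6 * max(1.0, np.abs(v).max()) or not np.isclose(
                np.linalg.norm(v), 1.0, atol=1e-6
            ):
                raise ValueError("normalized topography must be zero-mean unit-norm")

    def normalize(self) -> "Topography":
        v = self.values - self.values.mean()
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("cannot normalize a zero map")
        return Topography(v / n, self.montage, normalized=True)


# --------------------------------------------------------------------------
# EDF writing (EDF+C, 16-bit)
# --------------------------------------------------------------------------


def _ascii(value, width) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def write_recording(rec: Recording, path: str | os.PathLike, format: str = "EDF") -> None:
    """Write a Recording to disk; EO/EC blocks become standard annotations.

    Only EDF is supported for writing. Data are quantised to 16 bits over
    each channel's physical range; the recording is zero-padded to a whole
    number of 1-second data records.
    """
    if format != "EDF":
        raise FormatError(f"unsupported write format {format!r}")
    if rec.n_samples == 0:
        raise ValueError("cannot write a 0-sample recording")
    if rec.fs <= 0 or abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    fs = int(round(rec.fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((rec.n_channels, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    # physical scaling per channel (symmetric, strictly positive range)
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768
    scale = pmax / dig_max
    digital = np.clip(np.round(data / scale[:, None]), dig_min, dig_max).astype("<i2")

    n_sig = rec.n_channels + 1  # + annotation channel
    annot_len = 60  # bytes reserved per record for annotations

    tal_by_record: dict[int, bytes] = {}
    for b in rec.blocks:
        onset = b.start / rec.fs
        dur = (b.stop - b.start) / rec.fs
        tal = f"+{onset:.4f}\x15{dur:.4f}\x14{b.condition}\x14\x00".encode("ascii")
        ridx = min(int(onset), n_rec - 1)
        tal_by_record[ridx] = tal_by_record.get(ridx, b"") + tal

    buf = io.BytesIO()
    now = datetime.datetime(2000, 1, 1)
    header_bytes = 256 * (1 + n_sig)
    buf.write(_ascii("0", 8))
    buf.write(_ascii("X X X X", 80))
    buf.write(_ascii("Startdate 01-JAN-2000 X X X", 80))
    buf.write(_ascii(now.strftime("%d.%m.%y"), 8))
    buf.write(_ascii(now.strftime("%H.%M.%S"), 8))
    buf.write(_ascii(header_bytes, 8))
    buf.write(_ascii("EDF+C", 44))
    buf.write(_ascii(n_rec, 8))
    buf.write(_ascii(1, 8))  # record duration, seconds
    buf.write(_ascii(n_sig, 4))

    labels = list(rec.montage.labels) + ["EDF Annotations"]
    for lab in labels:
        buf.write(_ascii(lab, 16))
    for _ in labels:
        buf.write(_ascii("", 80))  # transducer
    for i in range(n_sig):
        buf.write(_ascii("uV" if i < rec.n_channels else "", 8))
    for i in range(n_sig):
        buf.write(_ascii(f"{-pmax[i]:.6g}" if i < rec.n_channels else -1, 8))
    for i in range(n_sig):
        buf.write(_ascii(f"{pmax[i]:.6g}" if i < rec.n_channels else 1, 8))
    for i in range(n_sig):
        buf.write(_ascii(dig_min if i < rec.n_channels else -32768, 8))
    for i in range(n_sig):
        buf.write(_ascii(dig_max if i < rec.n_channels else 32767, 8))
    for _ in labels:
        buf.write(_ascii("", 80))  # prefiltering
    for i in range(n_sig):
        buf.write(_ascii(fs if i < rec.n_channels else annot_len // 2, 8))
    for _ in labels:
        buf.write(_ascii("", 32))

    for r in range(n_rec):
        buf.write(digital[:, r * fs : (r + 1) * fs].tobytes())
        tal = f"+{r}\x14\x14\x00".encode("ascii") + tal_by_record.get(r, b"")
        if len(tal) > annot_len:
            raise ValueError("too many annotations in one record")
        buf.write(tal.ljust(annot_len, b"\x00"))

    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


# --------------------------------------------------------------------------
# reading (EDF and BrainVision, via mne)
# --------------------------------------------------------------------------


def read_recording(path: str | os.PathLike, format: str = "EDF") -> Recording:
    """Read an EDF or BrainVision file into a Recording (microvolts).

    EO/EC block boundaries are parsed from the file's annotations/markers;
    annotations whose description is (or ends with) "EO"/"EC" become blocks.
    """
    import mne

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if format == "EDF":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif format == "BrainVision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported format {format!r}")
    except FormatError:
        raise
    except Exception as exc:  # mne raises assorted exceptions on bad files
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc

    labels = [ch for ch in raw.ch_names]
    try:
        full = standard_1010_montage(62)
        montage = full.subset(labels)
    except (MontageError, ValueError) as exc:
        raise MontageError(f"unrecognised channel labels in {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # Volts -> microvolts
    fs = float(raw.info["sfreq"])
    blocks = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        cond = desc.strip().split("/")[-1]
        if cond in ("EO", "EC") and dur > 0:
            start = int(round(onset * fs))
            stop = int(round((onset + dur) * fs))
            blocks.append(Block(start, min(stop, data.shape[1]), cond))
    return Recording(data=data, fs=fs, montage=montage, blocks=blocks)
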