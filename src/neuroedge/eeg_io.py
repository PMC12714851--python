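"""Reading and writing EEG recordings plus montage management.

Two on-disk dialects are supported: EDF (European Data Format, 16-bit) and a
plain delimited numeric matrix (channels as columns, one header row of
labels).  The EDF codec here is a deliberately small, self-contained
implementation of the classic EDF header/record layout; it round-trips
anything this package writes and reads plain single-annotation-free EDF
files produced elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Montage",
    "EEGRecording",
    "load_montage",
    "read_recording",
    "write_recording",
]

_EDF_HEADER_BYTES = 256
_EDF_SIGNAL_HEADER_BYTES = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# Montages
# ---------------------------------------------------------------------------

# Row layout of the built-in 128-channel cap, front to back.  Each entry is
# (row label stem(s), lateral labels).  Coordinates are schematic: y runs
# anterior (+1) to posterior (-1), x left (-1) to right (+1).
_CAP128_ROWS: list[tuple[float, list[str]]] = [
    (1.00, ["Fp1", "Fpz", "Fp2"]),
    (0.90, ["AF7", "AF5", "AF3", "AF1", "AFz", "AF2", "AF4", "AF6", "AF8"]),
    (0.80, ["AFF5h", "AFF3h", "AFF1h", "AFF2h", "AFF4h", "AFF6h"]),
    (0.70, ["F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10"]),
    (0.60, ["FFC5h", "FFC3h", "FFC1h", "FFC2h", "FFC4h", "FFC6h"]),
    (0.50, ["FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10"]),
    (0.40, ["FCC5h", "FCC3h", "FCC1h", "FCC2h", "FCC4h", "FCC6h"]),
    (0.30, ["T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10"]),
    (0.20, ["CCP5h", "CCP3h", "CCP1h", "CCP2h", "CCP4h", "CCP6h"]),
    (0.10, ["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"]),
    (0.00, ["CPP5h", "CPP3h", "CPP1h", "CPP2h", "CPP4h", "CPP6h"]),
    (-0.15, ["P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10"]),
    (-0.30, ["PPO5h", "PPO3h", "PPO1h", "PPO2h", "PPO4h", "PPO6h"]),
    (-0.45, ["PO9", "PO7", "PO5", "PO3", "PO1", "POz", "PO2", "PO4", "PO6", "PO8", "PO10"]),
    (-0.60, ["POO5h", "POO3h", "POO1h", "POO2h", "POO4h", "POO6h"]),
    (-0.75, ["O1", "Oz", "O2"]),
    (-0.85, ["OI1h", "OI2h"]),
    (-0.95, ["I1", "Iz", "I2"]),
]


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout.

    Parameters
    ----------
    name:
        Identifier of the montage.
    channel_labels:
        Ordered, unique channel labels.
    positions:
        Optional ``(n_channels, 2)`` array of schematic scalp coordinates.
    """

    name: str
    channel_labels: tuple[str, ...]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(lab.lower() for lab in self.channel_labels)) != len(self.channel_labels):
            raise ValueError(f"montage {self.name!r} has duplicate channel labels")
        if self.positions is not None and len(self.positions) != len(self.channel_labels):
            raise ValueError("positions length must match channel_labels")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def _build_cap128() -> Montage:
    labels: list[str] = []
    pos: list[tuple[float, float]] = []
    for y, row in _CAP128_ROWS:
        n = len(row)
        for j, lab in enumerate(row):
            x = 0.0 if n == 1 else -1.0 + 2.0 * j / (n - 1)
            labels.append(lab)
            pos.append((x, y))
    assert len(labels) == 128, len(labels)
    return Montage("cap128", tuple(labels), np.asarray(pos, dtype=float))


_BUILTIN_MONTAGES: dict[str, Montage] = {
    "cap128": _build_cap128(),
    "wearable3": Montage(
        "wearable3",
        ("Fp1", "Fp2", "Fpz"),
        np.asarray([(-0.3, 1.0), (0.3, 1.0), (0.0, 1.0)], dtype=float),
    ),
}


def load_montage(name: str | Path) -> Montage:
    """Return a built-in montage (``"cap128"``/``"wearable3"``) or parse a file.

    Montage files are whitespace/comma-delimited text with one channel per
    line: ``label [x y]``.  Lines beginning with ``#`` are skipped.
    """
    key = str(name)
    if key in _BUILTIN_MONTAGES:
        return _BUILTIN_MONTAGES[key]
    path = Path(name)
    if not path.exists():
        raise ValueError(f"unknown montage {key!r} (not a built-in, not a file)")
    labels: list[str] = []
    pos: list[tuple[float, float]] = []
    has_pos = True
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        labels.append(parts[0])
        if len(parts) >= 3:
            pos.append((float(parts[1]), float(parts[2])))
        else:
            has_pos = False
    positions = np.asarray(pos, dtype=float) if (has_pos and pos) else None
    return Montage(path.stem, tuple(labels), positions)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """A multichannel EEG record in microvolts.

    ``data`` is ``(n_channels, n_samples)``; sample index ``t`` is 0-based and
    maps to time ``t / fs`` seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    eog_index: int | None = None
    session_id: str = ""
    t0: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_labels)} labels"
            )
        if self.eog_index is not None and not (0 <= self.eog_index < self.n_channels):
            raise ValueError("eog_index out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            fs=kw.get("fs", self.fs),
            channel_labels=list(kw.get("channel_labels", self.channel_labels)),
            eog_index=kw.get("eog_index", self.eog_index),
            session_id=kw.get("session_id", self.session_id),
            t0=kw.get("t0", self.t0),
        )


def _apply_nan_policy(data: np.ndarray, policy: str, where: str) -> np.ndarray:
    if np.all(np.isfinite(data)):
        return data
    if policy == "error":
        raise ValueError(f"non-finite samples in {where} (nan_policy='error')")
    if policy == "zero":
        warnings.warn(f"zero-filling non-finite samples in {where}", stacklevel=3)
        return np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    raise ValueError(f"unknown nan_policy {policy!r}")


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    labels: list[str] | None = None,
    nan_policy: str = "error",
) -> EEGRecording:
    """Read a recording from ``path``.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file suffix.  Matrix files need ``fs`` (labels come from the header
    row unless overridden).  Channel order is always file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "matrix":
        if fs is None:
            raise ValueError("matrix format requires fs")
        rec = _read_matrix(path, fs, labels)
    else:
        raise ValueError(f"unknown format {format!r}")
    rec.data = _apply_nan_policy(rec.data, nan_policy, str(path))
    return rec


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    """Write ``rec`` to ``path`` in the given (or suffix-inferred) format."""
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording (0 samples)")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix":
        _write_matrix(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# -- delimited matrix dialect ------------------------------------------------


def _matrix_delim(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _write_matrix(rec: EEGRecording, path: Path) -> None:
    delim = _matrix_delim(path)
    with open(path, "w") as fh:
        fh.write(delim.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=delim)


def _read_matrix(path: Path, fs: float, labels: list[str] | None) -> EEGRecording:
    delim = _matrix_delim(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty or missing header row")
        file_labels = [h.strip() for h in header.split(delim)]
        try:
            data = np.loadtxt(fh, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable numeric body: {exc}") from exc
    if labels is not None:
        if len(labels) != len(file_labels):
            raise ValueError(
                f"{len(labels)} labels supplied but file has {len(file_labels)} columns"
            )
        file_labels = list(labels)
    if data.shape[1] != len(file_labels):
        raise ValueError(f"{path}: {data.shape[1]} columns vs {len(file_labels)} labels")
    return EEGRecording(data=data.T, fs=fs, channel_labels=file_labels, session_id=path.stem)


# -- EDF dialect -------------------------------------------------------------


def _pad_ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt8(x: float) -> str:
    """Format a number into at most 8 ASCII characters."""
    for fmt in ("%d", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        if fmt == "%d" and x != int(x):
            continue
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode {x} in 8 EDF header characters")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    n_ch, n_samp = rec.data.shape
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("cannot write non-finite samples to EDF")
    duration = n_samp / rec.fs
    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X", 80),
            _pad_ascii(rec.session_id or "X", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(_EDF_HEADER_BYTES + n_ch * _EDF_SIGNAL_HEADER_BYTES), 8),
            _pad_ascii("", 44),
            _pad_ascii("1", 8),
            _pad_ascii(_fmt8(duration), 8),
            _pad_ascii(str(n_ch), 4),
        ]
    )
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    def col(values: list[str], width: int) -> bytes:
        return b"".join(_pad_ascii(v, width) for v in values)

    eog_tag = rec.eog_index
    sig_header = b"".join(
        [
            col([lab for lab in rec.channel_labels], 16),
            col(["EOG" if i == eog_tag else "AgAgCl electrode" for i in range(n_ch)], 80),
            col(["uV"] * n_ch, 8),
            col(["%.8g" % v for v in phys_min], 8),
            col(["%.8g" % v for v in phys_max], 8),
            col([str(_DIG_MIN)] * n_ch, 8),
            col([str(_DIG_MAX)] * n_ch, 8),
            col([""] * n_ch, 80),
            col([str(n_samp)] * n_ch, 8),
            col([""] * n_ch, 32),
        ]
    )
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())  # one data record, signal-sequential


def _read_edf(path: Path) -> EEGRecording:
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER_BYTES:
        raise ValueError(f"{path}: truncated EDF header")

    def ascii_field(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(ascii_field(236, 8))
        duration = float(ascii_field(244, 8))
        n_ch = int(ascii_field(252, 4))
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable EDF header: {exc}") from exc
    off = _EDF_HEADER_BYTES

    def sig_col(width: int) -> list[str]:
        nonlocal off
        vals = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n_ch)
        ]
        off += n_ch * width
        return vals

    labels = sig_col(16)
    transducers = sig_col(80)
    sig_col(8)  # physical dimension
    phys_min = np.array([float(v) for v in sig_col(8)])
    phys_max = np.array([float(v) for v in sig_col(8)])
    dig_min = np.array([float(v) for v in sig_col(8)])
    dig_max = np.array([float(v) for v in sig_col(8)])
    sig_col(80)  # prefiltering
    samples_per_rec = np.array([int(v) for v in sig_col(8)])
    sig_col(32)  # reserved

    if len(set(samples_per_rec)) != 1:
        raise ValueError(f"{path}: heterogeneous per-signal sampling is unsupported")
    spr = int(samples_per_rec[0])
    fs = spr / duration
    body = np.frombuffer(raw, dtype="<i2", offset=off)
    expect = n_records * n_ch * spr
    if body.size < expect:
        raise ValueError(f"{path}: EDF body shorter than header promises")
    records = body[:expect].reshape(n_records, n_ch, spr).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = np.concatenate(
        [(records[r] - dig_min[:, None]) * scale[:, None] + phys_min[:, None] for r in range(n_records)],
        axis=1,
    )
    eog_index = next((i for i, t in enumerate(transducers) if t.upper().startswith("EOG")), None)
    return EEGRecording(
        data=data,
        fs=round(fs, 6),
        channel_labels=labels,
        eog_index=eog_index,
        session_id=ascii_field(88, 80) or path.stem,
    )
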