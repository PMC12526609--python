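"""Readers and writers for the formats the staging pipeline touches.

Three kinds of input are supported:

* EDF polysomnography recordings (read through :mod:`mne`), from which a
  single bipolar derivation such as ``F4-F3`` is extracted;
* per-epoch hypnogram files, either plain one-label-per-line text or
  BIDS-style TSV with ``onset``/``duration``/stage columns;
* acquisition-board text exports — delimited numeric columns, one column
  per channel, framed in 10 s blocks of 10,000 samples at 1 kSPS.

A minimal 16-bit EDF *writer* is also provided so that synthetic
recordings can be exported and round-tripped through a real EDF reader.
All amplitudes are normalised to microvolts at read time: downstream
feature magnitudes (variance, SSI, band powers) are unit-sensitive.
"""

from __future__ import annotations

import datetime as _dt
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "Hypnogram",
    "BoardFrame",
    "STAGES",
    "UNSCORED",
    "canonical_stage",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_board_export",
    "temperature_from_reading",
]

#: Canonical five-class stage alphabet (AASM).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
#: Sentinel for epochs without a valid stage label.
UNSCORED = "UNSCORED"

#: Default alias table mapping common stage spellings to the canonical
#: alphabet.  Keys are matched case-insensitively.
DEFAULT_STAGE_ALIASES: dict[str, str] = {
    "w": "W", "wake": "W", "wk": "W", "stage w": "W", "0": "W",
    "n1": "N1", "s1": "N1", "1": "N1", "stage 1": "N1",
    "n2": "N2", "s2": "N2", "2": "N2", "stage 2": "N2",
    "n3": "N3", "s3": "N3", "3": "N3", "4": "N3", "s4": "N3",
    "sws": "N3", "stage 3": "N3", "stage 4": "N3",
    "r": "REM", "rem": "REM", "stage r": "REM", "5": "REM",
    "unscored": UNSCORED, "?": UNSCORED, "u": UNSCORED,
    "a": UNSCORED, "art": UNSCORED, "movement": UNSCORED, "-1": UNSCORED,
}


class ChannelNotFoundError(KeyError):
    """Requested EDF channel (or derivation operand) is absent."""


class FormatError(ValueError):
    """A file does not parse as the expected text/EDF layout."""


class VocabularyError(ValueError):
    """A hypnogram token is not in the stage alias table."""


@dataclass
class Recording:
    """A single-channel EEG trace in microvolts.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in µV.
    fs : float
        Sampling rate in Hz, > 0.
    derivation : str
        Channel-pair label, e.g. ``"F4-F3"``.
    start_time : datetime, optional
    subject_id : str
    """

    samples: np.ndarray
    fs: float
    derivation: str = ""
    start_time: _dt.datetime | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class Hypnogram:
    """Ordered per-epoch stage labels aligned to a recording start."""

    labels: list[str] = field(default_factory=list)
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        allowed = set(STAGES) | {UNSCORED}
        for lab in self.labels:
            if lab not in allowed:
                raise VocabularyError(f"label {lab!r} not in canonical alphabet")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_len

    def stage_at(self, t: float) -> str:
        """Stage of the half-open epoch [k·epoch_len, (k+1)·epoch_len) containing time ``t`` (s)."""
        if t < 0:
            return UNSCORED
        k = int(math.floor(t / self.epoch_len))
        if k >= len(self.labels):
            return UNSCORED
        return self.labels[k]


@dataclass
class BoardFrame:
    """One acquisition-board export frame: per-channel sample columns."""

    channels: np.ndarray  # (n_channels, n_samples)
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


def canonical_stage(token: str, aliases: dict[str, str] | None = None) -> str:
    """Map a stage token to the canonical alphabet, case-insensitively."""
    table = DEFAULT_STAGE_ALIASES if aliases is None else aliases
    key = token.strip().lower()
    if key in table:
        return table[key]
    raise VocabularyError(f"unrecognised stage token {token!r}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel_selector: str) -> Recording:
    """Read one channel — or a bipolar derivation ``"A-B"`` — from an EDF file.

    If ``channel_selector`` names an existing channel it is returned as-is.
    Otherwise, a selector of the form ``"A-B"`` is resolved as the
    sample-wise difference of the unipolar channels ``A`` and ``B``.
    Amplitudes are returned in microvolts.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - mne raises various types
        raise FormatError(f"{path} does not parse as EDF: {exc}") from exc

    names = raw.ch_names

    def _get(name: str) -> np.ndarray:
        matches = [c for c in names if c == name or c.split()[-1] == name]
        if not matches:
            raise ChannelNotFoundError(
                f"channel {name!r} not found in {path.name}; available: {names}"
            )
        return raw.get_data(picks=[matches[0]])[0] * 1e6  # V -> µV

    if channel_selector in names or channel_selector in [c.split()[-1] for c in names]:
        data = _get(channel_selector)
    elif "-" in channel_selector:
        a, b = channel_selector.split("-", 1)
        data = _get(a.strip()) - _get(b.strip())
    else:
        raise ChannelNotFoundError(
            f"channel {channel_selector!r} not found in {path.name}; available: {names}"
        )

    meas = raw.info.get("meas_date")
    start = None
    if meas is not None:
        start = meas.replace(tzinfo=None) if meas.tzinfo else meas
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        derivation=channel_selector,
        start_time=start,
        subject_id=str(raw.info.get("subject_info") or ""),
    )


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(
    path: str | Path,
    signals: dict[str, np.ndarray] | Recording,
    fs: float | None = None,
    start_time: _dt.datetime | None = None,
    patient_id: str = "X",
) -> None:
    """Write one or more µV channels to a 16-bit EDF file.

    Uses 1 s data records, so every channel length must be a whole
    multiple of ``fs``.  Quantisation is the EDF 16-bit step,
    ``(phys_max − phys_min)/(2¹⁶ − 2)`` per channel.
    """
    if isinstance(signals, Recording):
        fs = signals.fs
        start_time = start_time or signals.start_time
        signals = {signals.derivation or "EEG": signals.samples}
    if fs is None:
        raise ValueError("fs is required when passing a raw channel dict")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")

    labels = list(signals)
    arrays = [np.asarray(signals[k], dtype=float) for k in labels]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all channels must have equal length")
    if n % fs_int != 0:
        raise ValueError(
            f"channel length {n} is not a whole number of 1 s records at fs={fs_int}"
        )
    n_records = n // fs_int
    ns = len(labels)

    start_time = start_time or _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient_id, 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(start_time.strftime("%d.%m.%y"), 8),
        _edf_field(start_time.strftime("%H.%M.%S"), 8),
        _edf_field(str(256 * (ns + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(ns), 4),
    ])

    phys_min, phys_max, digitized = [], [], []
    for a in arrays:
        lo = float(np.min(a)) if a.size else -1.0
        hi = float(np.max(a)) if a.size else 1.0
        if hi <= lo:  # constant channel: widen so the scale is non-zero
            hi = lo + 1.0
        scale = (hi - lo) / 65534.0
        d = np.round((a - lo) / scale).astype(np.int64) - 32767
        digitized.append(np.clip(d, -32768, 32767).astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    def _num(x: float) -> str:
        s = f"{x:.8g}"
        return s[:8]

    header += b"".join(_edf_field(lab, 16) for lab in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_field(_num(v), 8) for v in phys_min)
    header += b"".join(_edf_field(_num(v), 8) for v in phys_max)
    header += b"".join(_edf_field("-32768", 8) for _ in labels)
    header += b"".join(_edf_field("32767", 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field(str(fs_int), 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * fs_int, (r + 1) * fs_int)
            for d in digitized:
                fh.write(d[sl].tobytes())


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(
    path: str | Path,
    epoch_len: float = 30.0,
    aliases: dict[str, str] | None = None,
) -> Hypnogram:
    """Read a per-epoch stage file (plain list or BIDS-style TSV).

    Plain format: one stage token per line.  TSV format is detected by a
    header line containing tab-separated column names; the stage column is
    the first of ``staging``/``stage``/``label``/``description``/
    ``trial_type`` present.  Tokens are canonicalised through the alias
    table; an unknown token raises :class:`VocabularyError` naming it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return Hypnogram(labels=[], epoch_len=epoch_len)

    first = lines[0]
    labels: list[str] = []
    if "\t" in first and any(c.isalpha() for c in first):
        header = [c.strip().lower() for c in first.split("\t")]
        stage_col = None
        for cand in ("staging", "stage", "label", "description", "trial_type"):
            if cand in header:
                stage_col = header.index(cand)
                break
        if stage_col is None:
            raise FormatError(
                f"no stage column among {header} in {path.name}"
            )
        for ln in lines[1:]:
            cells = ln.split("\t")
            labels.append(canonical_stage(cells[stage_col], aliases))
    else:
        for ln in lines:
            labels.append(canonical_stage(ln, aliases))
    return Hypnogram(labels=labels, epoch_len=epoch_len)


def write_hypnogram(path: str | Path, hyp: Hypnogram, style: str = "plain") -> None:
    """Write a hypnogram as plain labels or a BIDS-style TSV."""
    path = Path(path)
    if style == "plain":
        path.write_text("\n".join(hyp.labels) + ("\n" if hyp.labels else ""))
    elif style == "tsv":
        rows = ["onset\tduration\tstaging"]
        for i, lab in enumerate(hyp.labels):
            rows.append(f"{i * hyp.epoch_len:g}\t{hyp.epoch_len:g}\t{lab}")
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# Board exports
# ---------------------------------------------------------------------------

def read_board_export(path: str | Path, fs: float = 1000.0) -> BoardFrame:
    """Read an acquisition-board text export (one numeric column per channel).

    Delimiters may be whitespace or commas.  Ragged rows or non-numeric
    cells raise :class:`FormatError` naming the 1-based line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "%")):
                continue
            cells = line.replace(",", " ").split()
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: non-numeric value on line {lineno}"
                ) from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise FormatError(
                    f"{path.name}: ragged row on line {lineno} "
                    f"({len(values)} cells, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{path.name}: no numeric data")
    return BoardFrame(channels=np.asarray(rows, dtype=float).T, fs=fs)


# ---------------------------------------------------------------------------
# Device-side conversion
# ---------------------------------------------------------------------------

def temperature_from_reading(reading_uv: float) -> float:
    """Convert the acquisition front-end temperature-sensor voltage to °C.

    The sensor output follows ``T = (reading − 145,300 µV) / (490 µV/°C)
    + 25 °C`` (the 145,300 µV offset is the sensor reading at 25 °C; the
    datasheet prints it with a European thousands separator).  Affine, so
    each additional 490 µV adds exactly one degree.
    """
    reading_uv = float(reading_uv)
    if not math.isfinite(reading_uv):
        raise ValueError("temperature reading must be finite")
    return (reading_uv - 145300.0) / 490.0 + 25.0
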