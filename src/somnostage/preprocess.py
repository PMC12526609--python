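"""Signal conditioning and segmentation.

The conditioning chain mirrors standard sleep-EEG practice: a 0.2–44 Hz
band-pass to keep the delta-through-beta range while suppressing drift
and muscle noise, and a 50 Hz notch against mains interference, both
applied forward–backward (zero phase) so that spindles and slow
oscillations keep their temporal alignment.  The conditioned trace is
cut into 5 s analysis windows — non-overlapping for model training, or
with a configurable overlap whose final window is back-filled from
earlier samples so all windows share one length — and each window
inherits the stage of the 30 s epoch containing its start sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import Hypnogram, Recording, BoardFrame, UNSCORED

__all__ = [
    "FilterSpec",
    "Segment",
    "bandpass",
    "notch",
    "remove_common_mode",
    "segment_fixed",
    "segment_overlap",
    "assign_stage_labels",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    """Conditioning parameters (Hz unless noted)."""

    band_low: float = 0.2
    band_high: float = 44.0
    notch_freq: float = 50.0
    notch_q: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= fs / 2:
            raise ValueError(
                f"band_high={self.band_high} Hz is at/above Nyquist ({fs / 2} Hz)"
            )
        if self.notch_freq >= fs / 2:
            raise ValueError(
                f"notch_freq={self.notch_freq} Hz is at/above Nyquist ({fs / 2} Hz)"
            )


@dataclass
class Segment:
    """One fixed-length analysis window cut from a recording."""

    samples: np.ndarray
    fs: float
    start_index: int
    window_len: float = 5.0
    label: str = UNSCORED
    wrap_filled: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.window_len * self.fs))
        if self.samples.size != expected:
            raise ValueError(
                f"segment has {self.samples.size} samples, expected {expected}"
            )

    @property
    def start_time(self) -> float:
        """Window start in seconds from recording onset."""
        return self.start_index / self.fs


def _filtfilt(sos: np.ndarray, x: np.ndarray, fs: float,
              lowest_edge: float) -> np.ndarray:
    # mirror padding must cover the slowest transient: roughly three
    # periods of the lowest band edge (a 0.2 Hz high-pass settles over
    # seconds, far longer than the 3×order samples one might pad by).
    # Even extension keeps the signal and its slope continuous; odd
    # extension kinks the derivative and rings the low-frequency poles.
    padlen = int(3 * fs / lowest_edge)
    padlen = min(padlen, x.size - 1)
    return sps.sosfiltfilt(sos, x, padlen=padlen, padtype="even")


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Butterworth band-pass; zero-phase (forward–backward) by default.

    Realised as a high-pass/low-pass cascade: the band spans almost
    three decades (0.2–44 Hz), and a single band-pass section couples
    the slow 0.2 Hz pole into the response at every frequency, smearing
    transients over seconds.  Cascading keeps each section's settling
    time tied to its own corner.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos_hp = sps.butter(spec.order, spec.band_low, btype="highpass",
                        fs=rec.fs, output="sos")
    sos_lp = sps.butter(spec.order, spec.band_high, btype="lowpass",
                        fs=rec.fs, output="sos")
    if spec.zero_phase:
        y = _filtfilt(sos_hp, rec.samples, rec.fs, spec.band_low)
        y = _filtfilt(sos_lp, y, rec.fs, spec.band_high)
    else:
        y = sps.sosfilt(sos_lp, sps.sosfilt(sos_hp, rec.samples))
    return replace(rec, samples=y)


def notch(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """IIR notch at ``spec.notch_freq`` (mains), zero-phase by default."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=rec.fs)
    if spec.zero_phase:
        padlen = min(3 * max(len(a), len(b)), rec.samples.size - 1)
        y = sps.filtfilt(b, a, rec.samples, padlen=padlen)
    else:
        y = sps.lfilter(b, a, rec.samples)
    return replace(rec, samples=y)


def remove_common_mode(x: BoardFrame | Recording):
    """Subtract the common mode.

    Multi-channel input: at every time index the across-channel mean is
    removed from each channel.  Single-channel input: the channel's own
    temporal mean (DC) is removed.
    """
    if isinstance(x, Recording):
        return replace(x, samples=x.samples - x.samples.mean())
    ch = x.channels
    if ch.shape[0] == 1:
        out = ch - ch.mean(axis=1, keepdims=True)
    else:
        out = ch - ch.mean(axis=0, keepdims=True)
    return BoardFrame(channels=out, fs=x.fs)


def segment_fixed(rec: Recording, window_len: float = 5.0) -> list[Segment]:
    """Cut into contiguous non-overlapping windows; remainder discarded."""
    w = int(round(window_len * rec.fs))
    n = rec.samples.size
    if n < w:
        warnings.warn(
            f"recording ({n} samples) shorter than one {window_len} s window",
            stacklevel=2,
        )
        return []
    out = []
    for k in range(n // w):
        out.append(
            Segment(
                samples=rec.samples[k * w : (k + 1) * w],
                fs=rec.fs,
                start_index=k * w,
                window_len=window_len,
            )
        )
    return out


def segment_overlap(
    rec: Recording, window_len: float = 5.0, overlap_frac: float = 0.3
) -> list[Segment]:
    """Overlapping windows with a back-filled final window.

    Starts advance by ``window_len × (1 − overlap_frac)``.  If samples
    remain beyond the last fully contained window, one extra window is
    emitted that *ends* at the final sample and reaches back into earlier
    samples so every window has equal length; it is flagged
    ``wrap_filled``.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    w = int(round(window_len * rec.fs))
    step = int(round(w * (1.0 - overlap_frac)))
    if step == 0:
        raise ValueError("overlap too large: step of zero samples")
    n = rec.samples.size
    if n < w:
        warnings.warn("recording shorter than one window", stacklevel=2)
        return []
    out = []
    start = 0
    while start + w <= n:
        out.append(
            Segment(
                samples=rec.samples[start : start + w],
                fs=rec.fs,
                start_index=start,
                window_len=window_len,
            )
        )
        start += step
    last_end = out[-1].start_index + w
    if last_end < n:
        out.append(
            Segment(
                samples=rec.samples[n - w : n],
                fs=rec.fs,
                start_index=n - w,
                window_len=window_len,
                wrap_filled=True,
            )
        )
    return out


def assign_stage_labels(segments: list[Segment], hyp: Hypnogram) -> list[Segment]:
    """Label each window with the stage of the 30 s epoch containing its start.

    Epochs are half-open ``[t, t + epoch_len)``; windows starting beyond
    the hypnogram become ``UNSCORED``.  Labels are assigned in place and
    the list is returned for chaining.
    """
    for seg in segments:
        seg.label = hyp.stage_at(seg.start_time)
    return segments


def preprocess_recording(
    rec: Recording,
    hyp: Hypnogram | None = None,
    spec: FilterSpec | None = None,
    window_len: float = 5.0,
    overlap_frac: float = 0.0,
) -> list[Segment]:
    """Full conditioning chain: band-pass → notch → segment → label."""
    spec = spec or FilterSpec()
    rec = notch(bandpass(rec, spec), spec)
    if overlap_frac > 0:
        segs = segment_overlap(rec, window_len, overlap_frac)
    else:
        segs = segment_fixed(rec, window_len)
    if hyp is not None:
        assign_stage_labels(segs, hyp)
    return segs
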