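"""Multi-domain EEG feature bank for 5 s sleep-staging windows.

Each analysis window is summarised by a named vector of (by default) 100
features spanning three domains:

* **time domain** — amplitude statistics (max/min/mean/median, RMS,
  percentiles, IQR, variance, skewness, kurtosis), zero-crossing rate,
  average amplitude change, clearance factor, simple square integral,
  and the three Hjorth parameters (activity, mobility, complexity);
* **frequency domain** — Welch band powers and relative spectral powers
  over delta/theta/alpha/beta/gamma, band energies, total power, absolute
  power in 8–16 Hz, classical power ratios (DAR, DTR, DTABR, …), slow-wave
  indices (DSI/TSI/ASI), per-band and broadband spectral slope, dominant
  frequency, harmonic parameters (spectral centroid, bandwidth, value at
  the centroid), and spectral-edge frequencies SEF50/SEF95 with their
  difference SEFd computed over 2 s sub-epochs;
* **non-linear** — normalised spectral entropy, SVD (embedding) entropy,
  Rényi entropy of the amplitude distribution, and Lempel–Ziv (LZ76)
  complexity of the median-binarised signal.

The default bank is padded to exactly 100 names with per-band statistics
of the band-filtered signal (ZCR, RMS, AAC, variance, Hjorth
mobility/complexity and selected kurtoses).  The manifest is explicit,
versioned, and swappable; conventions such as non-excess kurtosis and
the n−1 variance denominator are fixed so every value is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps

from .preprocess import Segment

__all__ = [
    "BandScheme",
    "PSDEstimate",
    "FeatureVector",
    "DegenerateSegmentError",
    "DEFAULT_BANK",
    "BANK_VERSION",
    "time_domain_features",
    "hjorth_parameters",
    "welch_psd",
    "band_powers",
    "power_ratios",
    "slow_wave_indices",
    "spectral_slope",
    "dominant_frequency",
    "harmonic_parameters",
    "sef_difference",
    "spectral_entropy",
    "svd_entropy",
    "renyi_entropy",
    "lempel_ziv_complexity",
    "extract_features",
    "features_dataframe",
]

BANK_VERSION = "somnostage-bank-v1"


class DegenerateSegmentError(ValueError):
    """Raised when a window carries no usable signal (zero variance/power)."""


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands (Hz).

    Delta, theta and beta edges follow the usual sleep-EEG convention
    (0.5–4, 4–7, 13–30 Hz); alpha is 8–13 Hz and gamma is capped at the
    44 Hz analysis limit.  ``ap_band`` is the 8–16 Hz range whose
    absolute power covers the alpha/spindle-sigma region.
    """

    bands: dict = field(default_factory=lambda: {
        "delta": (0.5, 4.0),
        "theta": (4.0, 7.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 44.0),
    })
    analysis_range: tuple = (0.5, 44.0)
    ap_band: tuple = (8.0, 16.0)

    @property
    def band_names(self) -> tuple:
        return tuple(self.bands)


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a regular frequency grid."""

    freqs: np.ndarray
    density: np.ndarray  # µV²/Hz
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.size != self.density.size:
            raise ValueError("freqs and density must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        self.density = np.maximum(self.density, 0.0)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass
class FeatureVector:
    """Named feature values for one window."""

    values: dict
    segment_index: int = -1
    bank_version: str = BANK_VERSION
    degenerate: bool = False

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def time_domain_features(x: np.ndarray, fs: float) -> dict:
    """Seventeen amplitude/shape statistics of one window.

    Conventions: variance uses the n−1 denominator; skewness and
    kurtosis are the moment ratios m₃/m₂^1.5 and m₄/m₂² (non-excess, so
    a Gaussian gives 3); both fall back to a flagged 0 on constant
    input.  ZCR counts sign changes of the mean-removed signal per
    second; AAC is the mean absolute first difference; the clearance
    factor is max|x| / (mean √|x|)²; SSI is Σx².
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    var = float(np.var(x, ddof=1))
    xm = x - x.mean()
    s = np.sign(xm)
    s = s[s != 0]
    zc = int(np.count_nonzero(s[1:] != s[:-1])) if s.size > 1 else 0
    denom_cf = float(np.mean(np.sqrt(np.abs(x)))) ** 2
    m2 = float(np.mean(xm ** 2))
    if m2 > 0:
        skew = float(np.mean(xm ** 3)) / m2 ** 1.5
        kurt = float(np.mean(xm ** 4)) / m2 ** 2
    else:
        skew = kurt = 0.0  # sentinel for constant windows
    return {
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "mean": float(np.mean(x)),
        "median": float(p50),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "iqr": float(p75 - p25),
        "variance": var,
        "std": float(np.sqrt(var)),
        "skewness": skew,
        "kurtosis": kurt,
        "zcr": zc * fs / x.size,
        "aac": float(np.mean(np.abs(np.diff(x)))),
        "clearance_factor": float(np.max(np.abs(x)) / denom_cf) if denom_cf > 0 else 0.0,
        "ssi": float(np.sum(x ** 2)),
    }


def hjorth_parameters(x: np.ndarray, fs: float) -> dict:
    """Hjorth activity, mobility and complexity.

    The derivative is the first difference scaled by ``fs``, so mobility
    has per-second units: a pure sinusoid of frequency f₀ gives
    mobility ≈ 2πf₀.  Activity is exactly the sample variance (n−1).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    act = float(np.var(x, ddof=1))
    if act == 0:
        raise DegenerateSegmentError("zero-variance window has no Hjorth mobility")
    d1 = np.diff(x) * fs
    d2 = np.diff(d1) * fs
    mob = math.sqrt(np.var(d1, ddof=1) / act)
    v1 = np.var(d1, ddof=1)
    if v1 == 0:
        raise DegenerateSegmentError("first difference has zero variance")
    mob_d = math.sqrt(np.var(d2, ddof=1) / v1)
    return {"activity": act, "mobility": mob, "complexity": mob_d / mob}


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def welch_psd(
    x: np.ndarray,
    fs: float,
    subwin_sec: float = 1.0,
    overlap: float = 0.5,
) -> PSDEstimate:
    """Welch PSD with Hamming sub-windows (density scaling, µV²/Hz)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(subwin_sec * fs))
    if nperseg > x.size:
        raise ValueError(
            f"sub-window of {nperseg} samples exceeds segment length {x.size}"
        )
    freqs, dens = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant", scaling="density",
    )
    return PSDEstimate(
        freqs=freqs, density=dens,
        params={"subwin_sec": subwin_sec, "overlap": overlap, "window": "hamming"},
    )


def _band_integral(psd: PSDEstimate, lo: float, hi: float) -> float:
    m = psd.band_mask(lo, hi)
    if np.count_nonzero(m) < 2:
        return 0.0
    return float(np.trapezoid(psd.density[m], psd.freqs[m]))


def band_powers(
    psd: PSDEstimate, scheme: BandScheme | None = None, window_len: float = 5.0
) -> dict:
    """Absolute power, relative spectral power and energy per band.

    ``P_band`` is the trapezoidal integral of the density over the band;
    ``RSP_band = P_band / P_total`` with the total over the analysis
    range; ``E_band = P_band × window_len``; ``ap_8_16`` is the absolute
    power over 8–16 Hz.
    """
    scheme = scheme or BandScheme()
    out: dict = {}
    total = _band_integral(psd, *scheme.analysis_range)
    if total <= 0:
        raise DegenerateSegmentError("zero total power in analysis range")
    out["total_power"] = total
    for name, (lo, hi) in scheme.bands.items():
        p = _band_integral(psd, lo, hi)
        out[f"power_{name}"] = p
        out[f"rsp_{name}"] = p / total
        out[f"energy_{name}"] = p * window_len
    out["ap_8_16"] = _band_integral(psd, *scheme.ap_band)
    return out


def power_ratios(powers: dict) -> dict:
    """Classical EEG band-power ratios.

    DAR = Pδ/Pα, DTR = Pδ/Pθ, DTABR = (Pδ+Pθ)/(Pα+Pβ) — slow over fast
    waves — plus the remaining pairwise ratios; ``theta_delta`` is by
    construction 1/DTR.
    """
    pd_, pt = powers["power_delta"], powers["power_theta"]
    pa, pb, pg = powers["power_alpha"], powers["power_beta"], powers["power_gamma"]
    for v in (pd_, pt, pa, pb, pg):
        if v <= 0:
            raise DegenerateSegmentError("zero band power in ratio denominator")
    return {
        "dar": pd_ / pa,
        "dtr": pd_ / pt,
        "dtabr": (pd_ + pt) / (pa + pb),
        "delta_beta": pd_ / pb,
        "delta_gamma": pd_ / pg,
        "theta_delta": pt / pd_,
        "theta_alpha": pt / pa,
        "theta_beta": pt / pb,
        "theta_gamma": pt / pg,
    }


def slow_wave_indices(powers: dict) -> dict:
    """Slow-wave dominance indices DSI, TSI, ASI."""
    pd_, pt, pa = powers["power_delta"], powers["power_theta"], powers["power_alpha"]
    if pt + pa <= 0 or pd_ + pa <= 0 or pd_ + pt <= 0:
        raise DegenerateSegmentError("zero denominator in slow-wave index")
    return {
        "dsi": pd_ / (pt + pa),
        "tsi": pt / (pd_ + pa),
        "asi": pa / (pd_ + pt),
    }


def spectral_slope(psd: PSDEstimate, lo: float, hi: float) -> float:
    """OLS slope of density vs frequency within [lo, hi] (µV²/Hz per Hz)."""
    m = psd.band_mask(lo, hi)
    if np.count_nonzero(m) < 3:
        raise ValueError(
            f"fewer than 3 PSD points in [{lo}, {hi}] Hz; increase resolution"
        )
    f, d = psd.freqs[m], psd.density[m]
    fbar = f.mean()
    return float(np.sum((f - fbar) * (d - d.mean())) / np.sum((f - fbar) ** 2))


def dominant_frequency(psd: PSDEstimate, scheme: BandScheme | None = None) -> float:
    """Frequency of maximum density in the analysis range; ties go low."""
    scheme = scheme or BandScheme()
    m = psd.band_mask(*scheme.analysis_range)
    if not np.any(m):
        raise ValueError("empty analysis range")
    d = psd.density[m]
    if np.all(d == 0):
        raise DegenerateSegmentError("all-zero density")
    return float(psd.freqs[m][int(np.argmax(d))])


def harmonic_parameters(psd: PSDEstimate, scheme: BandScheme | None = None) -> dict:
    """Spectral centroid, RMS bandwidth and density at the centroid."""
    scheme = scheme or BandScheme()
    m = psd.band_mask(*scheme.analysis_range)
    f, p = psd.freqs[m], psd.density[m]
    tot = float(np.sum(p))
    if tot <= 0:
        raise DegenerateSegmentError("zero total power for harmonic parameters")
    fc = float(np.sum(f * p) / tot)
    bw = float(np.sqrt(np.sum((f - fc) ** 2 * p) / tot))
    val = float(np.interp(fc, f, p))
    return {"harmonic_center": fc, "harmonic_bandwidth": bw, "harmonic_value": val}


def sef_difference(
    x: np.ndarray,
    fs: float,
    scheme: BandScheme | None = None,
    sub_epoch: float = 2.0,
) -> dict:
    """Mean SEF95 − SEF50 over non-overlapping 2 s sub-epochs.

    SEFq is the smallest frequency below which q of the power within
    the analysis range lies, found by linear interpolation on the
    cumulative band-power integral.  Zero-power sub-epochs are dropped
    from the mean; if all are dropped the window is degenerate.
    """
    scheme = scheme or BandScheme()
    x = np.asarray(x, dtype=float)
    w = int(round(sub_epoch * fs))
    if x.size < w:
        raise ValueError("segment shorter than one sub-epoch")
    sef50s, sef95s = [], []
    for k in range(x.size // w):
        seg = x[k * w : (k + 1) * w]
        psd = welch_psd(seg, fs, subwin_sec=min(1.0, sub_epoch))
        m = psd.band_mask(*scheme.analysis_range)
        f, d = psd.freqs[m], psd.density[m]
        if f.size < 3 or np.all(d == 0):
            continue
        cum = spi.cumulative_trapezoid(d, f, initial=0.0)
        if cum[-1] <= 0:
            continue
        sef50s.append(float(np.interp(0.50 * cum[-1], cum, f)))
        sef95s.append(float(np.interp(0.95 * cum[-1], cum, f)))
    if not sef50s:
        raise DegenerateSegmentError("no sub-epoch carried power")
    sef50 = float(np.mean(sef50s))
    sef95 = float(np.mean(sef95s))
    return {"sef50": sef50, "sef95": sef95, "sefd": sef95 - sef50}


# ---------------------------------------------------------------------------
# Non-linear
# ---------------------------------------------------------------------------

def spectral_entropy(psd: PSDEstimate, scheme: BandScheme | None = None) -> float:
    """Shannon entropy of the normalised PSD, scaled to [0, 1]."""
    scheme = scheme or BandScheme()
    m = psd.band_mask(*scheme.analysis_range)
    d = psd.density[m]
    tot = float(np.sum(d))
    if tot <= 0:
        raise DegenerateSegmentError("zero power: spectral entropy undefined")
    p = d / tot
    p = p[p > 0]
    h = -float(np.sum(p * np.log2(p)))
    return h / math.log2(d.size) if d.size > 1 else 0.0


def svd_entropy(x: np.ndarray, m: int = 10, tau: int = 1) -> float:
    """Entropy of the normalised singular values of a delay embedding.

    The trajectory matrix stacks windows ``x[i : i + m·tau : tau]``; the
    singular values are normalised to sum to one and their Shannon
    entropy is divided by log₂(m), so the result lies in [0, 1] (0 for a
    rank-one trajectory, e.g. a constant signal).
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(f"signal too short for embedding (m={m}, tau={tau})")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    traj = x[idx]
    s = np.linalg.svd(traj, compute_uv=False)
    tot = float(np.sum(s))
    if tot <= 0:
        return 0.0
    sb = s / tot
    sb = sb[sb > 1e-15]
    return -float(np.sum(sb * np.log2(sb))) / math.log2(m)


def renyi_entropy(x: np.ndarray, alpha: float = 2.0, bins: int = 16) -> float:
    """Rényi entropy (bits) of the amplitude histogram.

    Equal-width bins over [min, max]; Hα = log₂(Σ pᵅ)/(1−α).  A constant
    signal (zero amplitude range) returns 0.
    """
    if alpha == 1.0:
        raise ValueError("alpha must differ from 1 (use Shannon entropy)")
    x = np.asarray(x, dtype=float)
    if np.max(x) == np.min(x):
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(np.log2(np.sum(p ** alpha)) / (1.0 - alpha))


def _lz76_count_py(s: np.ndarray) -> int:
    n = s.size
    if n == 0:
        return 0
    c, l, i, k, kmax = 1, 1, 0, 1, 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    if k > 1:  # unfinished phrase at the end of the sequence
        c += 1
    return c


try:  # the exhaustive-history scan is quadratic; JIT it when numba is present
    from numba import njit as _njit

    _lz76_count = _njit(cache=False)(_lz76_count_py)
except Exception:  # pragma: no cover - numba always present in CI image
    _lz76_count = _lz76_count_py


def lempel_ziv_complexity(x: np.ndarray) -> dict:
    """LZ76 complexity of the median-binarised signal.

    ``c_raw`` is the phrase count of the binary sequence
    (x ≥ median → 1); ``c_norm = c_raw · log₂(n) / n`` approaches 1 for
    long random sequences.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    bits = (x >= np.median(x)).astype(np.int8)
    c = _lz76_count(bits)
    return {"lzc_raw": float(c), "lzc": c * math.log2(x.size) / x.size}


# ---------------------------------------------------------------------------
# Bank assembly
# ---------------------------------------------------------------------------

_TIME_NAMES = [
    "max", "min", "mean", "median", "rms", "p25", "p50", "p75", "iqr",
    "variance", "std", "skewness", "kurtosis", "zcr", "aac",
    "clearance_factor", "ssi",
]
_HJORTH_NAMES = ["activity", "mobility", "complexity"]
_BANDS = ["delta", "theta", "alpha", "beta", "gamma"]
_SPECTRAL_NAMES = (
    [f"power_{b}" for b in _BANDS]
    + [f"rsp_{b}" for b in _BANDS]
    + [f"energy_{b}" for b in _BANDS]
    + [f"slope_{b}" for b in _BANDS]
    + ["slope_broadband", "total_power", "ap_8_16"]
)
_RATIO_NAMES = [
    "dar", "dtr", "dtabr", "delta_beta", "delta_gamma",
    "theta_delta", "theta_alpha", "theta_beta", "theta_gamma",
]
_SWI_NAMES = ["dsi", "tsi", "asi"]
_HARMONIC_NAMES = ["harmonic_center", "harmonic_bandwidth", "harmonic_value"]
_SEF_NAMES = ["sef50", "sef95", "sefd"]
_NONLINEAR_NAMES = ["spectral_entropy", "svd_entropy", "renyi_entropy", "lzc"]
# Per-band statistics of the band-filtered signal pad the bank to 100.
_BANDSTAT_NAMES = (
    [f"zcr_{b}" for b in _BANDS]
    + [f"rms_{b}" for b in _BANDS]
    + [f"aac_{b}" for b in _BANDS]
    + [f"variance_{b}" for b in _BANDS]
    + [f"mobility_{b}" for b in _BANDS]
    + [f"complexity_{b}" for b in _BANDS]
    + [f"kurtosis_{b}" for b in ("delta", "theta", "alpha", "beta")]
)

DEFAULT_BANK: list[str] = (
    _TIME_NAMES + _HJORTH_NAMES + _SPECTRAL_NAMES + _RATIO_NAMES
    + _SWI_NAMES + _HARMONIC_NAMES + ["dominant_freq"] + _SEF_NAMES
    + _NONLINEAR_NAMES + _BANDSTAT_NAMES
)
assert len(DEFAULT_BANK) == 100, len(DEFAULT_BANK)
assert len(set(DEFAULT_BANK)) == 100


from functools import lru_cache


@lru_cache(maxsize=64)
def _band_sos(fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.99 * fs / 2)
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _bandpassed(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    return sps.sosfiltfilt(_band_sos(fs, lo, hi), x)


def extract_features(
    seg: Segment,
    scheme: BandScheme | None = None,
    bank: list[str] | None = None,
    segment_index: int = -1,
) -> FeatureVector:
    """Assemble the named feature vector for one window.

    Degenerate windows (zero variance or zero in-band power) are
    returned with spectral/non-linear values set to 0 and the
    ``degenerate`` flag raised, so callers can exclude them from
    training instead of imputing.
    """
    scheme = scheme or BandScheme()
    bank = list(DEFAULT_BANK if bank is None else bank)
    x, fs = seg.samples, seg.fs

    values: dict = {}
    degenerate = False
    values.update(time_domain_features(x, fs))

    try:
        values.update(hjorth_parameters(x, fs))
    except DegenerateSegmentError:
        degenerate = True
        values.update({"activity": 0.0, "mobility": 0.0, "complexity": 0.0})

    spectral_keys = (
        _SPECTRAL_NAMES + _RATIO_NAMES + _SWI_NAMES + _HARMONIC_NAMES
        + ["dominant_freq"] + _SEF_NAMES
        + ["spectral_entropy"]
    )
    try:
        psd = welch_psd(x, fs)
        powers = band_powers(psd, scheme, seg.window_len)
        values.update(powers)
        values.update(power_ratios(powers))
        values.update(slow_wave_indices(powers))
        for b, (lo, hi) in scheme.bands.items():
            values[f"slope_{b}"] = spectral_slope(psd, lo, hi)
        values["slope_broadband"] = spectral_slope(psd, *scheme.analysis_range)
        values["dominant_freq"] = dominant_frequency(psd, scheme)
        values.update(harmonic_parameters(psd, scheme))
        values.update(sef_difference(x, fs, scheme))
        values["spectral_entropy"] = spectral_entropy(psd, scheme)
    except DegenerateSegmentError:
        degenerate = True
        for k in spectral_keys:
            values.setdefault(k, 0.0)

    values["svd_entropy"] = svd_entropy(x)
    values["renyi_entropy"] = renyi_entropy(x)
    values.update(lempel_ziv_complexity(x))

    needed_bands = {n.split("_")[-1] for n in bank if n in _BANDSTAT_NAMES}
    for b in _BANDS:
        if b not in needed_bands:
            continue
        lo, hi = scheme.bands[b]
        xb = _bandpassed(x, fs, lo, hi)
        td = time_domain_features(xb, fs)
        values[f"zcr_{b}"] = td["zcr"]
        values[f"rms_{b}"] = td["rms"]
        values[f"aac_{b}"] = td["aac"]
        values[f"variance_{b}"] = td["variance"]
        values[f"kurtosis_{b}"] = td["kurtosis"]
        try:
            hj = hjorth_parameters(xb, fs)
            values[f"mobility_{b}"] = hj["mobility"]
            values[f"complexity_{b}"] = hj["complexity"]
        except DegenerateSegmentError:
            degenerate = True
            values[f"mobility_{b}"] = 0.0
            values[f"complexity_{b}"] = 0.0

    missing = [n for n in bank if n not in values]
    if missing:
        raise KeyError(f"unresolvable feature names: {missing}")
    out = {n: float(values[n]) for n in bank}
    bad = [n for n, v in out.items() if not math.isfinite(v)]
    if bad:
        degenerate = True
        for n in bad:
            out[n] = 0.0
    return FeatureVector(
        values=out, segment_index=segment_index, degenerate=degenerate
    )


def features_dataframe(
    segments: list[Segment],
    scheme: BandScheme | None = None,
    bank: list[str] | None = None,
    recording_id: str = "",
    drop_degenerate: bool = False,
):
    """Feature matrix for a list of labelled windows.

    Returns a :class:`pandas.DataFrame` with one row per window, columns
    in manifest order plus ``label``, ``segment_index``, ``recording_id``
    and ``degenerate``.
    """
    import pandas as pd

    bank = list(DEFAULT_BANK if bank is None else bank)
    rows, labels, idxs, degs = [], [], [], []
    for i, seg in enumerate(segments):
        fv = extract_features(seg, scheme, bank, segment_index=i)
        rows.append(fv.as_array(bank))
        labels.append(seg.label)
        idxs.append(seg.start_index)
        degs.append(fv.degenerate)
    df = pd.DataFrame(np.asarray(rows), columns=bank)
    df["label"] = labels
    df["segment_index"] = idxs
    df["recording_id"] = recording_id
    df["degenerate"] = degs
    if drop_degenerate:
        df = df[~df["degenerate"]].reset_index(drop=True)
    return df
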