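"""Synthetic single-channel polysomnography.

The generator produces stage-labelled nights so the whole pipeline can
be exercised without clinical data.  A first-order Markov chain at 30 s
resolution yields the hypnogram; each epoch of EEG is then synthesised
in the frequency domain as a sum of band-limited random-phase
components whose variances follow the stage's relative band-power
profile, over a weak 1/f background, plus stage-typical events: spindle
bursts (≈13 Hz) in N2, high-amplitude slow oscillations (<1 Hz) in N3
and alpha bursts in Wake.  Profiles encode the classic staging cues —
delta power dominant in N3, theta prominence in REM and N1, alpha/beta
in Wake — as simulator conventions with adjustable targets.

Everything is seeded and reproducible; an EDF + hypnogram-TSV export is
provided so the file readers can be tested on real round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Hypnogram, Recording, STAGES, write_edf, write_hypnogram
from .preprocess import FilterSpec, preprocess_recording

__all__ = [
    "StageProfile",
    "TransitionModel",
    "DEFAULT_PROFILES",
    "DEFAULT_TRANSITIONS",
    "simulate_hypnogram",
    "simulate_eeg",
    "simulate_night",
    "make_dataset",
    "export_night",
]

_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 44.0),
}

#: Relative band-power targets per stage (sum to 1 within each stage).
DEFAULT_PROFILES: dict = {
    "W":   {"delta": 0.15, "theta": 0.15, "alpha": 0.30, "beta": 0.30, "gamma": 0.10},
    "N1":  {"delta": 0.25, "theta": 0.40, "alpha": 0.15, "beta": 0.15, "gamma": 0.05},
    "N2":  {"delta": 0.45, "theta": 0.25, "alpha": 0.10, "beta": 0.15, "gamma": 0.05},
    "N3":  {"delta": 0.70, "theta": 0.15, "alpha": 0.05, "beta": 0.07, "gamma": 0.03},
    "REM": {"delta": 0.20, "theta": 0.40, "alpha": 0.15, "beta": 0.20, "gamma": 0.05},
}


@dataclass(frozen=True)
class StageProfile:
    """Spectral recipe of the generator.

    ``targets`` maps each stage to relative band-power fractions;
    ``background_frac`` is the share of total variance given to the 1/f
    background (exponent ``one_over_f_exponent``); ``amplitude_uv`` is
    the target RMS of each epoch in µV; ``event_amplitude`` scales the
    stage-typical bursts relative to the epoch RMS.
    """

    targets: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_PROFILES.items()
    })
    background_frac: float = 0.10
    one_over_f_exponent: float = 1.0
    amplitude_uv: float = 50.0
    event_amplitude: float = 1.2

    def __post_init__(self) -> None:
        for s, t in self.targets.items():
            vals = np.array(list(t.values()))
            if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0, atol=1e-6):
                raise ValueError(
                    f"profile for stage {s} must be non-negative and sum to 1"
                )


#: Overnight stage occupancy of a healthy adult (fractions of time in
#: W, N1, N2, N3, REM) used to build the default chain.
_STAGE_FRACTIONS = np.array([0.10, 0.10, 0.45, 0.15, 0.20])


def _reversible_matrix(pi: np.ndarray, switch_rate: float = 0.25) -> np.ndarray:
    """Stochastic matrix with stationary distribution ``pi``.

    Off-diagonal P_ij = switch_rate·π_j (detailed balance holds since
    π_i P_ij is symmetric), diagonal takes the remainder; mean bout
    length is one to a few minutes at 30 s epochs, in line with real
    sleep-stage bouts (N1 bouts in particular are brief).
    """
    k = pi.size
    m = switch_rate * np.tile(pi, (k, 1))
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


@dataclass(frozen=True)
class TransitionModel:
    """First-order Markov chain over stages at 30 s resolution."""

    matrix: np.ndarray = field(
        default_factory=lambda: _reversible_matrix(_STAGE_FRACTIONS)
    )
    initial: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    )
    states: tuple = STAGES

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.states), len(self.states)):
            raise ValueError("matrix must be k×k over the stage alphabet")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("rows of the transition matrix must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0) or np.any(self.initial < 0):
            raise ValueError("initial distribution must be stochastic")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, k])
        return v / v.sum()


DEFAULT_TRANSITIONS = TransitionModel()


def simulate_hypnogram(
    tm: TransitionModel | None = None,
    n_epochs: int = 960,
    seed: int = 0,
    epoch_len: float = 30.0,
) -> Hypnogram:
    """Sample a Markov-chain stage sequence (default 8 h of 30 s epochs)."""
    tm = tm or DEFAULT_TRANSITIONS
    rng = np.random.default_rng(seed)
    k = len(tm.states)
    state = rng.choice(k, p=tm.initial)
    labels = []
    for _ in range(n_epochs):
        labels.append(tm.states[state])
        state = rng.choice(k, p=tm.matrix[state])
    return Hypnogram(labels=labels, epoch_len=epoch_len)


def _band_component(rng, freqs, lo, hi, exponent, n, fs) -> np.ndarray:
    """Random-phase component confined to [lo, hi) with a 1/f^χ envelope,
    unit variance."""
    amp = np.zeros_like(freqs)
    m = (freqs >= lo) & (freqs < hi)
    if not np.any(m):
        return np.zeros(n)
    amp[m] = freqs[m] ** (-exponent / 2.0)
    phase = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_of(f0: float) -> str | None:
    for band, (lo, hi) in _BANDS.items():
        if lo <= f0 < hi:
            return band
    return None


def _events(rng, stage: str, n: int, fs: float, rms: float, amp: float):
    """Stage-typical transient activity.

    Returns the waveform and its variance contribution per band (each
    burst is narrowband, so its power is booked to the band holding its
    centre frequency); the caller deducts these from the band budgets so
    events reshape morphology without inflating band power.
    """
    out = np.zeros(n)
    var_by_band: dict = {}
    t = np.arange(n) / fs

    def burst(f0: float, dur: float, scale: float):
        start = rng.uniform(0, max(1e-6, n / fs - dur))
        env = np.exp(-0.5 * ((t - start - dur / 2) / (dur / 4)) ** 2)
        w = scale * rms * env * np.sin(
            2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
        )
        out[:] += w
        band = _band_of(f0)
        if band is not None:
            var_by_band[band] = var_by_band.get(band, 0.0) + float(np.mean(w ** 2))

    if stage == "N2":
        for _ in range(rng.integers(1, 4)):        # sleep spindles
            burst(rng.uniform(12.0, 14.0), 1.0, amp)
    elif stage == "N3":
        for _ in range(rng.integers(2, 5)):        # slow oscillations
            burst(rng.uniform(0.6, 1.2), 2.0, 1.5 * amp)
    elif stage == "W":
        for _ in range(rng.integers(1, 3)):        # alpha bursts
            burst(rng.uniform(9.0, 11.0), 1.0, amp)
    return out, var_by_band


def simulate_eeg(
    hyp: Hypnogram,
    profile: StageProfile | None = None,
    fs: float = 250.0,
    seed: int = 0,
    subject_id: str = "sim",
) -> Recording:
    """Synthesise a µV EEG trace following a hypnogram's stage sequence."""
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz to cover the gamma band")
    profile = profile or StageProfile()
    rng = np.random.default_rng(seed)
    n_ep = int(round(hyp.epoch_len * fs))
    freqs = np.fft.rfftfreq(n_ep, d=1.0 / fs)
    total_var = profile.amplitude_uv ** 2
    bg_var = total_var * profile.background_frac

    # share of the 1/f background's power falling in each named band, so
    # band budgets can be corrected for it
    bg_hi = min(45.0, 0.99 * fs / 2)
    bg_mask = (freqs >= 0.3) & (freqs < bg_hi)
    bg_psd = np.zeros_like(freqs)
    bg_psd[bg_mask] = freqs[bg_mask] ** (-profile.one_over_f_exponent)
    bg_share = {
        band: float(bg_psd[(freqs >= lo) & (freqs < hi)].sum() / bg_psd.sum())
        for band, (lo, hi) in _BANDS.items()
    }

    chunks = []
    for lab in hyp.labels:
        stage = lab if lab in profile.targets else "W"
        targets = profile.targets[stage]
        ev, ev_var = _events(rng, stage, n_ep, fs, profile.amplitude_uv,
                             profile.event_amplitude)
        x = ev.copy()
        for band, (lo, hi) in _BANDS.items():
            frac = targets.get(band, 0.0)
            if frac <= 0:
                continue
            # the band's budget is total_var×frac; events and background
            # already contribute, so the stochastic component fills the rest
            budget = total_var * frac
            comp_var = budget - ev_var.get(band, 0.0) - bg_var * bg_share[band]
            comp_var = max(comp_var, 0.05 * budget)
            comp = _band_component(rng, freqs, lo, min(hi, 0.99 * fs / 2),
                                   0.0, n_ep, fs)
            x += comp * np.sqrt(comp_var)
        bg = _band_component(rng, freqs, 0.3, bg_hi,
                             profile.one_over_f_exponent, n_ep, fs)
        x += bg * np.sqrt(bg_var)
        chunks.append(x)
    return Recording(
        samples=np.concatenate(chunks), fs=fs,
        derivation="F4-F3", subject_id=subject_id,
    )


def simulate_night(
    n_epochs: int = 960,
    fs: float = 250.0,
    seed: int = 0,
    tm: TransitionModel | None = None,
    profile: StageProfile | None = None,
    subject_id: str = "sim",
) -> tuple:
    """One night: (Recording, Hypnogram), both derived from ``seed``."""
    hyp = simulate_hypnogram(tm, n_epochs=n_epochs, seed=seed)
    rec = simulate_eeg(hyp, profile, fs=fs, seed=seed + 1,
                       subject_id=subject_id)
    return rec, hyp


def make_dataset(
    n_nights: int = 3,
    n_epochs: int = 960,
    fs: float = 250.0,
    seed: int = 0,
    tm: TransitionModel | None = None,
    profile: StageProfile | None = None,
    filter_spec: FilterSpec | None = None,
    bank=None,
):
    """Run the full front half of the pipeline on simulated nights.

    Each night is simulated, conditioned (band-pass + notch), segmented
    into labelled 5 s windows and featurised.  Returns a DataFrame with
    one row per window, the feature columns plus ``label`` and
    ``recording_id`` (recording boundaries preserved for sequence
    building).
    """
    import pandas as pd

    from .features import features_dataframe

    frames = []
    for night in range(n_nights):
        rec, hyp = simulate_night(
            n_epochs=n_epochs, fs=fs, seed=seed + 1000 * night,
            tm=tm, profile=profile, subject_id=f"night{night}",
        )
        segs = preprocess_recording(rec, hyp, spec=filter_spec)
        frames.append(
            features_dataframe(segs, bank=bank, recording_id=f"night{night}")
        )
    return pd.concat(frames, ignore_index=True)


def export_night(
    out_dir: str | Path,
    n_epochs: int = 960,
    fs: float = 250.0,
    seed: int = 0,
    stem: str = "sim",
) -> dict:
    """Write one simulated night as EDF + hypnogram TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, hyp = simulate_night(n_epochs=n_epochs, fs=fs, seed=seed)
    edf_path = out_dir / f"{stem}.edf"
    hyp_path = out_dir / f"{stem}_hypnogram.tsv"
    write_edf(edf_path, {"F4-F3": rec.samples}, fs=rec.fs)
    write_hypnogram(hyp_path, hyp, style="tsv")
    return {"edf": edf_path, "hypnogram": hyp_path, "seed": seed}
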