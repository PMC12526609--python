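# Methods

## Problem and model

Sleep staging assigns one of five AASM stages — Wake, N1, N2, N3, REM —
to each 30 s epoch of a night's EEG. `somnostage` does this from a
single frontal derivation, which is the regime of wearable headbands
and self-applied home monitoring: no occipital channels, no EOG or EMG.
The working hypothesis is that a broad, physiologically grounded
feature set over short (5 s) windows, compressed by mutual-information
ranking and PCA, carries enough information for a small recurrent
network to stage sleep reliably.

The classifier is hierarchical. Stage 1 solves the easier three-class
problem Wake / REM / NREM, where wake is marked by alpha–beta activity,
REM by mixed-frequency theta-rich activity, and NREM by slow-wave
dominance. Stage 2, trained only on NREM windows, separates N1
(transitional), N2 (spindles, intermediate slow-wave content) and N3
(high-amplitude delta). The cascade is exhaustive and exclusive: stage 1
finalises W and REM; windows routed to stage 2 are spliced back
index-aligned, with an internal guard that aborts on any count
mismatch between the two passes.

Each network is an attention-augmented LSTM over sequences of T
consecutive window feature vectors:

    LSTM(128, L2) → batch norm → temporal attention →
    LSTM(64, L2) → batch norm → dropout 0.3 →
    dense 64 ReLU → dropout 0.2 → softmax

The attention block scores each hidden state `s_t = v·tanh(W h_t + b)`,
softmax-normalises the scores over time and rescales each hidden vector
by its weight, keeping the sequence shape for the second LSTM rather
than pooling to a single context vector. Training minimises weighted
categorical cross-entropy — class weights `n/(k·n_c)` with the REM
class multiplied by a configurable boost (default 1.5) — using AdamW
with learning rate 5·10⁻⁴ and decoupled weight decay 10⁻⁴, plus an
explicit L2 penalty (10⁻⁴) on the four LSTM weight matrices.

The networks run on `somnostage.nn`, a compact NumPy reverse-mode
autodiff engine written for this package (tape of 2-D arrays, sequences
as per-timestep lists). Every primitive's gradient is checked against
central finite differences in the test suite, and a full-model gradient
check covers the composed architecture.

### Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `window_len` | 5 s | analysis window; six windows tile one 30 s epoch |
| `timesteps` T | 6 | sequence context = one clinical scoring epoch; the label is the final window's |
| `band_low`, `band_high` | 0.2, 44 Hz | EEG band retained by conditioning |
| `notch_freq`, Q | 50 Hz, 30 | mains interference |
| mRMR bins | 10 quantile bins | plug-in MI estimator, log₂ (bits) |
| relevance threshold | 0.01 bits | mRMR score floor; estimator-relative (see below) |
| PCA variance threshold | 94% or 98% | smallest k reaching the cumulative target |
| `lstm1/lstm2/dense` | 128/64/64 | network widths |
| `dropout1/dropout2` | 0.3/0.2 | regularisation after LSTM-2 and the dense layer |
| `lr`, `weight_decay`, `l2_coeff` | 5·10⁻⁴, 10⁻⁴, 10⁻⁴ | AdamW + LSTM L2 |
| `epochs`, `batch_size` | 50, 128 | training budget (tests use 10 epochs) |
| `rem_boost` | 1.5 | extra weight on the REM class |

## Feature bank

The default bank is exactly 100 named features: 17 amplitude statistics,
3 Hjorth parameters, per-band absolute power / relative power / energy
(5 bands × 3), per-band + broadband spectral slope (6), total power,
absolute power 8–16 Hz, 9 power ratios, 3 slow-wave indices, 3 harmonic
parameters (spectral centroid, RMS bandwidth, density at the centroid),
dominant frequency, SEF50/SEF95/SEFd, 4 non-linear features, padded to
100 with statistics of the band-filtered signal (ZCR, RMS, AAC,
variance, Hjorth mobility/complexity per band, and four per-band
kurtoses). The manifest is an explicit ordered list
(`somnostage.features.DEFAULT_BANK`), versioned and swappable.

Conventions fixed so every value is testable:

* variance uses the n−1 denominator; kurtosis is non-excess (Gaussian →
  3); both skewness and kurtosis fall back to a flagged 0 on constant
  windows;
* Hjorth derivatives are first differences scaled by fs, so mobility of
  a pure f₀ sinusoid is ≈ 2πf₀ (per-second convention);
* PSD: Welch, 1 s Hamming sub-windows, 50% overlap, density scaling;
  band powers are trapezoidal integrals; the analysis range is
  0.5–44 Hz; alpha is 8–13 Hz and gamma 30–44 Hz;
* spectral slope is ordinary least squares of raw density vs frequency
  (per band and broadband), not log–log;
* SEF50/SEF95 are interpolated on the cumulative in-band integral of
  2 s sub-epoch PSDs; SEFd is the mean of (SEF95−SEF50);
* Rényi entropy (order 2) is computed on a 16-bin amplitude histogram —
  an amplitude-domain, not spectral, quantity, so it can move
  independently of spectral entropy;
* SVD entropy uses a delay embedding (m = 10, τ = 1), singular values
  normalised to sum 1, entropy divided by log₂ m;
* Lempel–Ziv uses LZ76 exhaustive-history parsing of the
  median-binarised signal, final partial phrase counted, normalised by
  n/log₂ n;
* dominant-frequency ties break toward the lower frequency;
* degenerate windows (zero variance or zero in-band power) are flagged
  and excluded from training, never imputed.

## Selection

Mutual information is the plug-in estimate on a joint frequency table
after equal-frequency discretisation into 10 bins (labels used as-is),
in bits. The mRMR ranking is greedy: the first pick maximises relevance
I(x, y); each later pick maximises MIQ = V_x / W_x with W_x the mean MI
against the already-selected set; ties break by column order, making
the trace bit-reproducible. A candidate with positive relevance and
zero measured redundancy is an infinitely good pick. The batch
redundancy definition (mean pairwise MI including self-terms) is kept
as a separate diagnostic (`redundancy_batch`).

Because the 0.01 relevance threshold is meaningful only relative to an
MI estimator, rankings from different estimators are not comparable;
with this estimator and well-separated synthetic data most of the bank
clears the threshold, whereas on real data the same threshold prunes
heavily. Features are z-scored before PCA — magnitudes in the bank span
many orders (variance and SSI in µV² vs entropies in [0, 1]) and
unstandardised PCA would be dominated by the former.

## Synthetic data

The generator emulates what the pipeline needs to see, not sleep
microstructure. A first-order Markov chain at 30 s resolution produces
the hypnogram; its default transition matrix is reversible with
stationary distribution matched to healthy-adult overnight stage
occupancy (W 10%, N1 10%, N2 45%, N3 15%, REM 20%) and a switch rate
giving bout lengths of one to a few minutes. Each epoch's EEG is
synthesised in the frequency domain: random-phase band-limited
components whose variances follow the stage's relative band-power
profile, a weak 1/f background (10% of total variance), and
stage-typical events — spindle bursts (12–14 Hz) in N2, high-amplitude
slow oscillations (0.6–1.2 Hz) in N3, alpha bursts in Wake. Event and
background power are *deducted* from the owning band's budget, so the
generated signal honours its band-power targets by construction; the
parameter-recovery test confirms ≤ 15% relative error per band per
stage. Default amplitude is 50 µV RMS; default rate 250 Hz (tests use
128 Hz).

Two measurement caveats, verified during development: 1 s Welch
sub-windows cannot resolve the <1 Hz slow oscillations (recovery is
therefore measured with 4 s sub-windows on 30 s epochs), and the
0.2–44 Hz conditioning filter, applied forward–backward, attenuates
the top of the 30–44 Hz gamma band by design — recovery is measured on
the raw generated signal.

What the generator does **not** emulate: K-complex and sawtooth
morphology, artifacts (ocular, muscular, cardiac), inter-subject
variability, electrode drift, or realistic stage-transition semantics
(e.g. sleep-onset latency, REM cycling). Passing tests therefore
demonstrate that the pipeline machinery is correct and that the
cascade can learn cleanly separable stage signatures — not that it
reaches any particular accuracy on clinical recordings.

## Numerical choices

* **Band-pass realisation.** The 0.2–44 Hz pass-band spans almost three
  decades. A single SOS Butterworth band-pass couples the 0.2 Hz pole
  into the response at all frequencies, smearing transients over
  seconds: a pure 60 Hz tone retained 16–33% of its RMS. The filter is
  therefore realised as a 4th-order high-pass plus 4th-order low-pass
  cascade, each applied forward–backward with *even* (mirror) padding of
  about three periods of the corner frequency — odd reflection kinks
  the derivative at the boundary and rings the slow pole. Residual at
  60 Hz: 3.9%.
* **Batch normalisation momentum** is 0.9 (not the Keras-style 0.99):
  running statistics must converge within the few hundred optimizer
  steps of a short training run, or inference-mode normalisation stays
  biased toward its initialisation.
* **Stage-2 training set** is ground-truth NREM windows, not stage-1
  predictions, avoiding compounded label noise; at inference the
  cascade necessarily routes stage-1's NREM predictions.
* **Splits.** 80/20 stratified on the five-class label, deterministic
  given the seed; optional stratified k-fold CV inside the training
  split. Sequences never cross recording boundaries; the first T−1
  windows of each recording are left-padded by repeating the earliest
  vector.
* **Epoch boundaries** are half-open [t, t+30); a window belongs to the
  epoch containing its start sample.
* **Overlap segmentation** (30% option) advances starts by
  window×(1−overlap); if samples remain after the last contained
  window, one extra window ending at the final sample is emitted,
  back-filled from earlier samples and flagged `wrap_filled`.
* **EDF writing** uses 1 s records and 16-bit quantisation with
  per-channel physical scaling; round-trips are exact to the
  quantisation step. Reading goes through MNE and normalises amplitudes
  to microvolts.
* **Report rounding** is 3 decimals for display; raw values are kept
  internally. Zero-support or zero-prediction classes produce flagged
  zeros, never exceptions, so audits of external tables cannot abort.
  Note that aggregates recomputed from 3-decimal per-class tables are
  themselves only accurate to about one rounding unit.

## Problem sizes

Desk-scale runs use 2 h nights (240 epochs) at 128 Hz: four nights
yield 5 760 labelled windows, feature extraction runs at ≈ 8 ms per
window, and the full two-network training at 10 epochs takes under a
minute on one CPU core. The generator's own defaults remain 8 h nights
at 250 Hz. The end-to-end check trains on three nights and stages a
fourth, unseen night, reaching ≈ 96% five-class accuracy with the
default profiles.

## Known limitations

* Accuracy figures on synthetic nights say nothing quantitative about
  clinical data; the stage profiles are deliberately well separated.
* The mRMR relevance threshold is estimator-relative (see above).
* The NumPy networks are CPU-bound and favour clarity over speed; at
  full clinical scale (tens of thousands of windows, 50 epochs) training
  takes tens of minutes.
* No artifact rejection (ICA/regression) is included; heavily
  contaminated recordings will degrade the feature bank.
* Hypnogram file parsing covers plain label lists and BIDS-style TSV;
  proprietary scoring formats need conversion.
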