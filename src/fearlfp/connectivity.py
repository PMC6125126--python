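"""dmPFC-BLA theta coherence and directional lead/lag.

Coherence is Welch magnitude-squared coherence (500 ms Hamming windows,
1024-point FFT, 50% overlap), summarized as the mean over 2-12 Hz.

Lead/lag uses amplitude cross-correlation: each signal is zero-phase
bandpass filtered to 2-12 Hz, its instantaneous (Hilbert) amplitude is
demeaned, and the two envelopes are Pearson-correlated at every integer
sample lag in [-0.1, +0.1] s, normalizing over the overlapping samples
only.  Positive lag means the dmPFC envelope leads the BLA envelope.
Significance comes from a shift-surrogate null: one envelope is
circularly shifted by a random 2-5 s offset (random sign) 100 times and
the observed correlation peak must exceed 95% of the surrogate peaks.
The summary lead/lag of a timepoint is the center of the maximal 5 ms
bin of the per-segment peak-lag histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, coherence as _welch_coherence, get_window, \
    hilbert, sosfiltfilt, correlate

THETA_BAND = (2.0, 12.0)


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coherence: np.ndarray     # magnitude-squared, in [0, 1]
    theta_summary: float
    window_s: float = 0.5
    nfft: int = 1024


@dataclass
class LeadLagResult:
    peak_lags: np.ndarray         # s, one per segment
    peak_values: np.ndarray       # Pearson r at the peak
    surrogate_peaks: np.ndarray   # pooled over segments
    significant: bool
    summary_lag: float            # s, histogram-maximum bin center
    bin_width: float = 0.005
    n_surrogates: int = 100
    seed: int | None = None

    def exceedance_fraction(self) -> float:
        """Fraction of surrogate peaks below the observed (median) peak;
        the significance flag is recomputable as this fraction > 0.95."""
        actual = float(np.median(self.peak_values))
        return float(np.mean(actual > self.surrogate_peaks))


def coherence_spectrum(x, y, rate: float, window_s: float = 0.5,
                       nfft: int = 1024,
                       band: tuple[float, float] = THETA_BAND) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence between two equal-length segments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("segments must have equal length")
    nperseg = int(round(window_s * rate))
    if x.size < nperseg:
        raise ValueError("segment shorter than one Welch window")
    f, c = _welch_coherence(x, y, fs=rate, window=get_window("hamming", nperseg),
                            nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft)
    m = (f >= band[0]) & (f <= band[1])
    return CoherenceSpectrum(freqs=f, coherence=c,
                             theta_summary=float(c[m].mean()),
                             window_s=window_s, nfft=nfft)


def theta_envelope(signal, rate: float, band: tuple[float, float] = THETA_BAND,
                   order: int = 4) -> np.ndarray:
    """Demeaned instantaneous amplitude of the theta-band component.

    Zero-phase (forward-backward) Butterworth bandpass so the filter
    itself introduces no inter-channel delay, then the modulus of the
    analytic signal, minus its mean.
    """
    x = np.asarray(signal, dtype=float)
    if band[1] >= rate / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    if x.size < 3 * order * 3:
        raise ValueError("signal shorter than the filter transient")
    sos = butter(order, band, btype="bandpass", fs=rate, output="sos")
    env = np.abs(hilbert(sosfiltfilt(sos, x)))
    return env - env.mean()


def envelope_xcorr(env_a, env_b, rate: float, max_lag: float = 0.1):
    """Pearson correlation of two envelopes at every sample lag in
    [-max_lag, +max_lag], each lag normalized over the overlapping
    samples only.

    Positive lag means ``env_a`` (dmPFC) leads ``env_b`` (BLA): the
    correlation at lag k compares env_a[:n-k] with env_b[k:].
    Returns (lags_s, r, peak_lag_s, peak_r).
    """
    a = np.asarray(env_a, dtype=float)
    b = np.asarray(env_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("envelopes must have equal length")
    n = a.size
    L = int(round(max_lag * rate))
    if L >= n // 2:
        raise ValueError("max_lag must be below half the segment duration")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance envelope")

    # raw sliding cross-products via FFT, then exact per-lag Pearson
    # normalization from prefix sums over the overlap
    full = correlate(b, a, mode="full", method="auto")  # full[n-1+k] = sum a[t] b[t+k]
    ks = np.arange(-L, L + 1)
    cross = full[n - 1 + ks]

    pa = np.concatenate(([0.0], np.cumsum(a)))
    pa2 = np.concatenate(([0.0], np.cumsum(a * a)))
    pb = np.concatenate(([0.0], np.cumsum(b)))
    pb2 = np.concatenate(([0.0], np.cumsum(b * b)))

    m = n - np.abs(ks)
    pos = ks >= 0
    sa = np.where(pos, pa[np.minimum(n - ks, n)], pa[n] - pa[np.minimum(-ks, n)])
    sa2 = np.where(pos, pa2[np.minimum(n - ks, n)], pa2[n] - pa2[np.minimum(-ks, n)])
    nk = np.clip(n + ks, 0, n)
    sb = np.where(pos, pb[n] - pb[np.minimum(ks, n)], pb[nk])
    sb2 = np.where(pos, pb2[n] - pb2[np.minimum(ks, n)], pb2[nk])

    cov = cross - sa * sb / m
    var_a = sa2 - sa * sa / m
    var_b = sb2 - sb * sb / m
    denom = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    lags = ks / rate
    i = int(np.argmax(r))
    return lags, r, float(lags[i]), float(r[i])


def surrogate_peaks(env_a, env_b, rate: float, n: int = 100,
                    shift_range: tuple[float, float] = (2.0, 5.0),
                    rng: np.random.Generator | int | None = None,
                    max_lag: float = 0.1) -> np.ndarray:
    """Chance cross-correlation peaks from circular time shifts.

    Each replicate circularly shifts ``env_b`` by a uniform 2-5 s offset
    with random sign, recomputes the lagged Pearson correlation, and
    stores its peak value.  The circular shift preserves envelope
    autocorrelation and segment length.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    b = np.asarray(env_b, dtype=float)
    dur = b.size / rate
    if dur <= 2 * shift_range[1]:
        raise ValueError("segment too short for the surrogate shift range")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    peaks = np.empty(n)
    for i in range(n):
        shift = rng.uniform(*shift_range) * (1 if rng.random() < 0.5 else -1)
        shifted = np.roll(b, int(round(shift * rate)))
        _, _, _, peaks[i] = envelope_xcorr(env_a, shifted, rate, max_lag)
    return peaks


def _histogram_mode(values: np.ndarray, max_lag: float, bin_width: float) -> float:
    """Center of the maximal histogram bin; ties resolved toward the
    smallest |center|, then the positive one."""
    nbins = int(round(2 * max_lag / bin_width)) + 1
    edges = (np.arange(nbins + 1) - 0.5) * bin_width - max_lag
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    best = np.flatnonzero(counts == counts.max())
    best = best[np.lexsort((-centers[best], np.abs(centers[best])))]
    return float(np.round(centers[best[0]], 9))


def lead_lag(segments, rate: float, n_surrogates: int = 100,
             seed: int | None = None, max_lag: float = 0.1,
             bin_width: float = 0.005,
             shift_range: tuple[float, float] = (2.0, 5.0)) -> LeadLagResult:
    """Summary lead/lag over a timepoint's analysis segments.

    ``segments`` is a list of (envelope_dmPFC, envelope_BLA) pairs —
    normally the 30 s CS windows of the timepoint's two trials.  Per
    segment the cross-correlation peak (lag and value) is collected and
    ``n_surrogates`` shift-surrogate peaks are generated; significance
    requires the median observed peak to exceed 95% of the pooled
    surrogate peaks, and the summary lag is the center of the maximal
    ``bin_width`` bin of the per-segment peak-lag histogram.
    """
    if not segments:
        raise ValueError("need at least one segment")
    rng = np.random.default_rng(seed)
    lags, vals, surr = [], [], []
    for env_a, env_b in segments:
        _, _, pl, pv = envelope_xcorr(env_a, env_b, rate, max_lag)
        lags.append(pl)
        vals.append(pv)
        surr.append(surrogate_peaks(env_a, env_b, rate, n_surrogates,
                                    shift_range, rng, max_lag))
    lags = np.asarray(lags)
    vals = np.asarray(vals)
    surr = np.concatenate(surr)
    actual = float(np.median(vals))
    significant = bool(np.mean(actual > surr) > 0.95)
    return LeadLagResult(peak_lags=lags, peak_values=vals, surrogate_peaks=surr,
                         significant=significant,
                         summary_lag=_histogram_mode(lags, max_lag, bin_width),
                         bin_width=bin_width, n_surrogates=n_surrogates,
                         seed=seed)


def cs_window_segments(rec, trial_indices, rate: float | None = None):
    """Theta-envelope pairs for the 30 s CS windows of the given trials."""
    rate = rec.rate if rate is None else rate
    segs = []
    for k in trial_indices:
        row = rec.trials[rec.trials["trial_index"] == int(k)].iloc[0]
        i0 = int(round(float(row["tone_onset_s"]) * rate))
        i1 = i0 + int(round(rec.tone_duration * rate))
        ea = theta_envelope(rec.channels["dmPFC"][i0:i1], rate)
        eb = theta_envelope(rec.channels["BLA"][i0:i1], rate)
        segs.append((ea, eb))
    return segs
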