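"""Morlet-wavelet time-frequency maps of averaged evoked responses and
evoked theta-power quantification.

The transform uses the complex Morlet family in the bandwidth/center
(``fb``/``fc``) parameterization, psi(t) = (pi*fb)^(-1/2) exp(-t^2/fb)
exp(j*2*pi*fc*t), with fb = 2 and fc = 1 Hz, so the scale mapped to an
analysis frequency f at sampling rate fs is a = fc*fs/f.  Power is
expressed in dB, z-scored per frequency row across the full epoch, and
the mean baseline (pre-onset) value of each row is subtracted; evoked
theta power is the mean of the normalized map over 0-250 ms and 2-12 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

DB_FLOOR = 1e-12


def default_freq_grid() -> np.ndarray:
    """2-100 Hz in 0.1 Hz steps."""
    return np.round(np.arange(20, 1001) * 0.1, 10)


@dataclass
class TFMap:
    power: np.ndarray         # (n_times, n_freqs); dB before normalization
    times_ms: np.ndarray      # relative to pip onset
    freqs: np.ndarray         # Hz
    fb: float = 2.0
    fc: float = 1.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    normalized: bool = False


def _wavelet_sigma_samples(freq: float, rate: float, fb: float, fc: float) -> float:
    # time-domain Gaussian SD of the scaled wavelet, in samples
    scale = fc * rate / freq
    return scale * np.sqrt(fb / 2.0)


def morlet_tfr(waveform: np.ndarray, rate: float, times_ms: np.ndarray,
               freqs: np.ndarray | None = None, fb: float = 2.0, fc: float = 1.0,
               pad: str = "reflect") -> TFMap:
    """Continuous wavelet transform of one evoked waveform; |CWT|^2 in dB.

    The epoch is short relative to the lowest-frequency wavelet, so it is
    padded (reflection by default, length = one wavelet support, 4 sigma,
    at the lowest frequency) before the transform and cropped after; the
    cone of influence is not masked.
    """
    w = np.asarray(waveform, dtype=float)
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > rate / 2:
        raise ValueError("frequency grid exceeds the Nyquist frequency")
    wavelet = pywt.ContinuousWavelet(f"cmor{fb}-{fc}")
    scales = pywt.frequency2scale(wavelet, freqs / rate)
    pad_len = int(np.ceil(4 * _wavelet_sigma_samples(freqs.min(), rate, fb, fc)))
    if pad == "none":
        padded, off = w, 0
    else:
        padded = np.pad(w, pad_len, mode=pad)
        off = pad_len
    if padded.size < 2:
        raise ValueError("waveform too short for the wavelet transform")
    coef, _ = pywt.cwt(padded, scales, wavelet, sampling_period=1.0 / rate,
                       method="fft")
    power = np.abs(coef[:, off:off + w.size]) ** 2  # (n_freqs, n_times)
    power_db = 10.0 * np.log10(np.maximum(power, DB_FLOOR))
    return TFMap(power=power_db.T, times_ms=np.asarray(times_ms, dtype=float),
                 freqs=freqs, fb=fb, fc=fc)


def zscore_and_baseline(tf: TFMap) -> TFMap:
    """Per-frequency z-score over the full epoch, then per-frequency
    subtraction of the mean over the baseline window [-200, 0) ms."""
    if tf.normalized:
        raise ValueError("map is already normalized")
    p = tf.power
    mu = p.mean(axis=0)
    sd = p.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero variance in frequency row(s) {tf.freqs[dead][:5]} Hz")
    z = (p - mu) / sd
    b0, b1 = tf.baseline_ms
    bmask = (tf.times_ms >= b0) & (tf.times_ms < b1)
    if not bmask.any():
        raise ValueError("baseline window lies outside the time axis")
    z = z - z[bmask].mean(axis=0)
    return replace(tf, power=z, normalized=True)


def evoked_theta_power(tf: TFMap, window_ms: tuple[float, float] = (0.0, 250.0),
                       band: tuple[float, float] = (2.0, 12.0)) -> float:
    """Mean normalized power over the evoked window x theta band
    (half-open time window [0, 250) ms, inclusive 2-12 Hz band)."""
    if not tf.normalized:
        raise ValueError("normalize the map first (zscore_and_baseline)")
    tmask = (tf.times_ms >= window_ms[0]) & (tf.times_ms < window_ms[1])
    fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not tmask.any() or not fmask.any():
        raise ValueError("map axes do not cover the requested window/band")
    if tf.times_ms.min() > window_ms[0] or tf.times_ms.max() < window_ms[1] - 1e-9:
        raise ValueError("time axis does not cover the evoked window")
    if tf.freqs.min() > band[0] or tf.freqs.max() < band[1]:
        raise ValueError("frequency axis does not cover the theta band")
    return float(tf.power[np.ix_(tmask, fmask)].mean())
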