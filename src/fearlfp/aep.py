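"""Pip-aligned evoked-potential averaging and peak-trough amplitude scoring.

The auditory evoked potential (AEP) is the mean LFP deflection
time-locked to the pip onsets of the scored trials; its amplitude is the
difference between the first post-onset peak and the first following
trough, reported in microvolts and normalized per animal as a percent of
the before-conditioning baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)


class NoDeflectionError(ValueError):
    """No qualifying peak/trough pair in the search window (distinct from
    a scored amplitude of zero)."""


@dataclass
class EvokedResponse:
    waveform: np.ndarray      # µV
    times_ms: np.ndarray      # relative to pip onset
    n_pips: int
    region: str = ""
    timepoint: str = ""
    amplitude: float | None = None       # µV, peak - trough
    peak_latency_ms: float | None = None
    trough_latency_ms: float | None = None


def epoch_pips(rec, trial_indices, region: str,
               window_ms: tuple[float, float] = (-100.0, 400.0)) -> np.ndarray:
    """One baseline-corrected segment per pip of the selected trials.

    Each segment spans ``window_ms`` around its pip onset and has its own
    mean over the pre-onset part of the window subtracted.  Pips whose
    window would cross a recording edge are dropped (count logged).
    Returns an (n_segments, n_times) array.
    """
    x = np.asarray(rec.channels[region], dtype=float)
    rate = rec.rate
    i_lo = int(round(window_ms[0] * rate / 1000.0))
    i_hi = int(round(window_ms[1] * rate / 1000.0))
    segs, dropped = [], 0
    for k in trial_indices:
        for onset in rec.pip_onsets(int(k)):
            i0 = int(round(onset * rate))
            if i0 + i_lo < 0 or i0 + i_hi > x.size:
                dropped += 1
                continue
            seg = x[i0 + i_lo:i0 + i_hi].copy()
            base = seg[: -i_lo] if i_lo < 0 else seg[:0]
            if base.size:
                seg -= base.mean()
            segs.append(seg)
    if dropped:
        log.info("epoch_pips: dropped %d pip(s) too close to recording edge", dropped)
    if not segs:
        raise ValueError("no pip segments fit inside the recording")
    return np.asarray(segs)


def epoch_times_ms(window_ms: tuple[float, float] = (-100.0, 400.0),
                   rate: float = 1000.0) -> np.ndarray:
    i_lo = int(round(window_ms[0] * rate / 1000.0))
    i_hi = int(round(window_ms[1] * rate / 1000.0))
    return np.arange(i_lo, i_hi) * 1000.0 / rate


def average_aep(segments: np.ndarray, times_ms: np.ndarray | None = None,
                region: str = "", timepoint: str = "",
                rate: float = 1000.0) -> EvokedResponse:
    """Pointwise arithmetic mean over pip segments."""
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2 or segments.shape[0] == 0:
        raise ValueError("need a non-empty (n_segments, n_times) array")
    if times_ms is None:
        times_ms = np.arange(segments.shape[1]) * 1000.0 / rate
    return EvokedResponse(waveform=segments.mean(axis=0),
                          times_ms=np.asarray(times_ms, dtype=float),
                          n_pips=segments.shape[0],
                          region=region, timepoint=timepoint)


def score_amplitude(evoked: EvokedResponse,
                    search_window_ms: tuple[float, float] = (0.0, 250.0),
                    prominence_floor: float | None = None) -> EvokedResponse:
    """First-peak minus first-trough amplitude of an averaged AEP.

    The peak is the first local maximum after onset whose prominence
    exceeds the floor (default: twice the SD of the pre-onset baseline
    period); the trough is the first local minimum after that peak.  The
    scored amplitude is invariant to adding a constant and scales
    linearly with waveform gain.
    """
    w = np.asarray(evoked.waveform, dtype=float)
    t = np.asarray(evoked.times_ms, dtype=float)
    lo, hi = search_window_ms
    if t[0] > lo or t[-1] < hi - 1e-9:
        raise ValueError("waveform does not cover the search window")
    if prominence_floor is None:
        base = w[t < 0]
        prominence_floor = 2.0 * base.std() if base.size else 0.0
    floor = max(prominence_floor, 1e-12 * (np.ptp(w) + 1.0))

    in_win = (t >= lo) & (t < hi)
    idx_win = np.flatnonzero(in_win)
    seg = w[idx_win]
    peaks, _ = find_peaks(seg, prominence=floor)
    if peaks.size == 0:
        raise NoDeflectionError("no qualifying peak in the search window")
    p = peaks[0]
    troughs, _ = find_peaks(-seg, prominence=floor)
    troughs = troughs[troughs > p]
    if troughs.size == 0:
        raise NoDeflectionError("no trough after the first peak")
    q = troughs[0]
    evoked.amplitude = float(seg[p] - seg[q])
    evoked.peak_latency_ms = float(t[idx_win[p]])
    evoked.trough_latency_ms = float(t[idx_win[q]])
    return evoked


def normalize_percent(value: float, baseline: float) -> float:
    """``100 * value / baseline`` (baseline must be positive)."""
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * value / baseline
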