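"""Synthetic dual-region LFP generator with known ground truth.

Emulates the recording conditions of a rat auditory fear-conditioning
experiment with simultaneous dmPFC and BLA local field potentials:
1 kHz sampling, 1-500 Hz band-limited signals, 30-s conditioned-stimulus
tones built from 30 pips at 1 Hz, 80-160 s inter-trial intervals.

The two channels share a band-limited theta source with a configurable
directional delay (positive lag = dmPFC leads BLA) and a mixing weight
(``coupling``) controlling the fraction of BLA theta variance that is
shared with the dmPFC.  Each pip adds a fast auditory-evoked-potential
template and a slower pip-locked theta burst; the per-region, per-trial
theta gain scales the burst (the component the evoked theta-power
analysis measures), while the ongoing theta amplitude is set separately
by ``theta_sd`` so that coherence and lead/lag are governed by
``coupling`` and ``lag`` alone.

Everything is driven by a single seeded generator per session, so a
(params, design, seed) triple fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("dmPFC", "BLA")

SESSION_LABELS = (
    "context_habituation",
    "tone_habituation",
    "conditioning",
    "fear_recall_extinction",
    "extinction_recall",
)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SessionDesign:
    """Trial layout of one behavioral session.

    Defaults follow the standard protocol: a 30 s tone of 30 pips
    (100 ms, 1 Hz), inter-trial intervals drawn uniformly from 80-160 s
    (mean 120 s), and a 0.5 s / 0.7 mA foot shock co-terminating with the
    tone during conditioning (the shock is metadata only; no artifact is
    simulated).
    """

    session_label: str = "tone_habituation"
    n_tones: int = 5
    pips_per_tone: int = 30
    pip_rate: float = 1.0          # Hz
    pip_duration_ms: float = 100.0
    tone_duration: float = 30.0    # s
    iti_mean: float = 120.0        # s
    iti_range: tuple[float, float] = (80.0, 160.0)
    us_duration: float = 0.5       # s, conditioning only
    us_amplitude_record: float = 0.7  # mA, metadata only
    pre_roll: float = 35.0         # s of signal before the first tone
    post_roll: float = 5.0         # s after the last tone

    def __post_init__(self) -> None:
        if self.session_label not in SESSION_LABELS:
            raise ValueError(f"unknown session_label {self.session_label!r}")
        if self.n_tones < 1:
            raise ValueError("n_tones must be >= 1")
        if not np.isclose(self.pips_per_tone / self.pip_rate, self.tone_duration):
            raise ValueError(
                "pips_per_tone / pip_rate must equal tone_duration "
                f"({self.pips_per_tone}/{self.pip_rate} != {self.tone_duration})"
            )
        lo, hi = self.iti_range
        if not (lo <= self.iti_mean <= hi):
            raise ValueError("iti_mean must lie inside iti_range")


def default_design(label: str, n_tones: int | None = None) -> SessionDesign:
    """Standard session designs: 5 tones for habituation, 15 for the
    fear-recall/extinction and extinction-recall sessions.  The number of
    CS-US pairings during conditioning must be given explicitly."""
    if n_tones is None:
        if label == "tone_habituation":
            n_tones = 5
        elif label in ("fear_recall_extinction", "extinction_recall"):
            n_tones = 15
        else:
            raise ValueError(f"n_tones required for session {label!r}")
    return SessionDesign(session_label=label, n_tones=n_tones)


def _per_trial(value, n_trials: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_trials, arr.item())
    if arr.size != n_trials:
        raise ValueError(f"{name} must be scalar or length n_trials={n_trials}")
    return arr


@dataclass
class SimulationParams:
    """Physical parameters of the simulated recording.

    Amplitudes are in microvolts. ``region_theta_gain`` and
    ``aep_amplitude`` accept either a scalar per region or one value per
    trial; ``coupling`` is the fraction of BLA theta variance shared with
    the dmPFC and ``lag`` (seconds) is positive when the dmPFC leads.
    """

    sampling_rate: float = 1000.0
    band_limits: tuple[float, float] = (1.0, 500.0)
    theta_source_band: tuple[float, float] = (4.0, 10.0)
    coupling: float = 0.9
    lag: float = 0.02
    theta_sd: float = 30.0               # µV, ongoing theta SD at gain 1
    region_theta_gain: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"dmPFC": 1.0, "BLA": 1.0})
    aep_amplitude: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"dmPFC": 75.0, "BLA": 75.0})  # peak-trough µV
    evoked_theta_uv: float = 15.0        # µV, pip-locked burst peak at gain 1
    evoked_theta_freq: float = 8.0       # Hz
    evoked_theta_jitter: float = 0.2     # per-pip amplitude jitter (lognormal sd)
    noise_sd: float = 15.0               # µV, pink background
    pink_noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if abs(self.lag) >= 2.0:
            raise ValueError("|lag| must be < 2 s")
        if self.sampling_rate < 2 * self.band_limits[1]:
            raise ValueError("upper band limit must not exceed the Nyquist frequency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be non-negative")


@dataclass
class GroundTruth:
    """Per-trial injected values, serialized alongside the signals."""

    session_label: str
    seed: int
    lag: float
    coupling: float
    theta_gain: dict          # region -> list per trial
    aep_amplitude: dict       # region -> list per trial
    freeze_frac: list | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# noise primitives
# ---------------------------------------------------------------------------

def band_limited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float], sd: float = 1.0) -> np.ndarray:
    """Gaussian noise with spectral support restricted to ``band`` (hard
    frequency-domain mask) and sample standard deviation exactly ``sd``."""
    from scipy.fft import next_fast_len

    # synthesize at an FFT-friendly length and keep the first n samples;
    # the process is stationary so the slice has the same spectrum
    m = next_fast_len(n)
    x = rng.standard_normal(m)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(m, 1.0 / rate)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, m)[:n]
    s = y.std()
    if s == 0:
        return y
    return y * (sd / s)


def pink_noise(rng: np.random.Generator, n: int, rate: float,
               band: tuple[float, float], exponent: float = 1.0,
               sd: float = 1.0) -> np.ndarray:
    """1/f^exponent background noise, band-limited to ``band``."""
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    spec = np.fft.rfft(rng.standard_normal(m))
    f = np.fft.rfftfreq(m, 1.0 / rate)
    shape = np.zeros_like(f)
    mask = (f >= band[0]) & (f <= band[1]) & (f > 0)
    shape[mask] = f[mask] ** (-exponent / 2.0)
    y = np.fft.irfft(spec * shape, m)[:n]
    s = y.std()
    if s == 0:
        return y
    return y * (sd / s)


# ---------------------------------------------------------------------------
# evoked waveforms
# ---------------------------------------------------------------------------

def make_aep_template(peak_uv: float, trough_uv: float,
                      peak_latency_ms: float = 15.0,
                      trough_latency_ms: float = 30.0,
                      duration_ms: float = 60.0,
                      rate: float = 1000.0) -> np.ndarray:
    """Biphasic evoked-potential template: one positive then one negative
    deflection, zero at both ends.

    Built from two raised-cosine lobes centred at the requested latencies
    and iteratively rescaled so the sampled maximum equals ``peak_uv`` and
    the minimum equals ``trough_uv`` exactly (the lobes overlap, so a
    one-shot scaling would miss).  Consequently the peak-trough amplitude
    scored on the template is ``peak_uv - trough_uv``.
    """
    for v in (peak_uv, trough_uv, peak_latency_ms, trough_latency_ms, duration_ms):
        if not np.isfinite(v):
            raise ValueError("non-finite template parameter")
    if not (0 < peak_latency_ms < trough_latency_ms < duration_ms):
        raise ValueError("need 0 < peak_latency < trough_latency < duration")
    n = int(round(duration_ms * rate / 1000.0)) + 1
    t = np.arange(n) * 1000.0 / rate  # ms

    def lobe(center: float, halfwidth: float) -> np.ndarray:
        out = np.zeros(n)
        m = np.abs(t - center) < halfwidth
        out[m] = np.cos(np.pi * (t[m] - center) / (2 * halfwidth)) ** 2
        return out

    w = trough_latency_ms - peak_latency_ms
    bp = lobe(peak_latency_ms, min(w, peak_latency_ms))
    bt = lobe(trough_latency_ms, min(w, duration_ms - trough_latency_ms))

    if peak_uv == 0 and trough_uv == 0:
        return np.zeros(n)
    alpha, beta = max(peak_uv, 0.0), max(-trough_uv, 0.0)
    w_out = alpha * bp - beta * bt
    scale = max(abs(peak_uv), abs(trough_uv))
    for _ in range(60):
        hi, lo = w_out.max(), w_out.min()
        if abs(hi - peak_uv) < 1e-12 * scale and abs(lo - trough_uv) < 1e-12 * scale:
            break
        if alpha > 0 and hi > 0:
            alpha *= peak_uv / hi
        if beta > 0 and lo < 0:
            beta *= trough_uv / lo
        w_out = alpha * bp - beta * bt
    return w_out


def make_theta_burst(amplitude_uv: float, freq: float = 8.0,
                     center_ms: float = 120.0, sd_ms: float = 50.0,
                     duration_ms: float = 300.0,
                     rate: float = 1000.0) -> np.ndarray:
    """Pip-locked evoked theta transient: a Gaussian-windowed sinusoid
    starting at pip onset. This is the component that carries the
    'auditory evoked theta' measured by the time-frequency analysis."""
    n = int(round(duration_ms * rate / 1000.0)) + 1
    t = np.arange(n) / rate  # s
    env = np.exp(-0.5 * ((t - center_ms / 1000.0) / (sd_ms / 1000.0)) ** 2)
    return amplitude_uv * env * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def _event_times(design: SessionDesign, rng: np.random.Generator):
    """Tone onsets, pip onsets, and optional shock onsets for one session."""
    tone_onsets = []
    tcur = design.pre_roll
    for _ in range(design.n_tones):
        tone_onsets.append(tcur)
        tcur += design.tone_duration + rng.uniform(*design.iti_range)
    tone_onsets = np.asarray(tone_onsets)
    pip_onsets = tone_onsets[:, None] + np.arange(design.pips_per_tone)[None, :] / design.pip_rate
    duration = tone_onsets[-1] + design.tone_duration + design.post_roll
    us_onsets = None
    if design.session_label == "conditioning":
        us_onsets = tone_onsets + design.tone_duration - design.us_duration
    return tone_onsets, pip_onsets, us_onsets, duration


def simulate_session(design: SessionDesign, params: SimulationParams,
                     animal_id: str = "sim00", group: str = "control",
                     freeze_frac: Sequence[float] | None = None):
    """Simulate one two-channel session.

    Returns a ``(SessionRecording, GroundTruth)`` pair.  Construction:
    a shared band-limited theta source drives both regions, the BLA copy
    delayed by ``lag`` and mixed with a private theta source by
    variance-preserving weights sqrt(coupling) / sqrt(1-coupling); each
    region is scaled by its per-trial theta gain over the tone windows,
    and every pip adds the AEP template plus the theta burst; pink
    background noise completes the channel.
    """
    from .session_io import SessionRecording  # local import to avoid cycle

    rate = params.sampling_rate
    if abs(params.lag) >= design.iti_range[0]:
        raise ValueError("lag must be shorter than the shortest ITI")

    rng = np.random.default_rng(params.seed)
    tone_onsets, pip_onsets, us_onsets, duration = _event_times(design, rng)
    n = int(round(duration * rate))
    nt = design.n_tones

    gains = {r: _per_trial(params.region_theta_gain[r], nt, f"theta_gain[{r}]")
             for r in REGIONS}
    aeps = {r: _per_trial(params.aep_amplitude[r], nt, f"aep_amplitude[{r}]")
            for r in REGIONS}

    # shared + private theta sources; extra margin so the delayed copy is
    # drawn from the same realization
    lag_samp = int(round(params.lag * rate))
    margin = abs(lag_samp) + 1
    shared = band_limited_noise(rng, n + 2 * margin, rate, params.theta_source_band)
    private = band_limited_noise(rng, n, rate, params.theta_source_band)
    s_dm = shared[margin:margin + n]
    s_bla_shared = shared[margin - lag_samp:margin - lag_samp + n]

    c = params.coupling
    theta = {
        "dmPFC": s_dm,
        "BLA": np.sqrt(c) * s_bla_shared + np.sqrt(1.0 - c) * private,
    }

    channels = {}
    base_template = make_aep_template(40.0, -35.0, rate=rate)
    base_amp = base_template.max() - base_template.min()  # 75 µV
    for r in REGIONS:
        # ongoing theta amplitude is fixed by theta_sd; the per-trial
        # theta gain scales only the pip-locked evoked burst below (the
        # quantity the evoked theta-power analysis measures)
        x = theta[r] * params.theta_sd
        # pip-locked components
        for k in range(nt):
            tmpl = base_template * (aeps[r][k] / base_amp)
            for onset in pip_onsets[k]:
                i0 = int(round(onset * rate))
                seg = tmpl
                if i0 + seg.size > n:
                    seg = seg[: n - i0]
                x[i0:i0 + seg.size] += seg
                jit = float(np.exp(rng.normal(0.0, params.evoked_theta_jitter))) \
                    if params.evoked_theta_jitter > 0 else 1.0
                burst = make_theta_burst(
                    params.evoked_theta_uv * gains[r][k] * jit,
                    freq=params.evoked_theta_freq, rate=rate)
                bseg = burst[: max(0, min(burst.size, n - i0))]
                x[i0:i0 + bseg.size] += bseg
        if params.noise_sd > 0:
            x = x + pink_noise(rng, n, rate, params.band_limits,
                               params.pink_noise_exponent, params.noise_sd)
        channels[r] = x

    trials = pd.DataFrame({
        "trial_index": np.arange(1, nt + 1),
        "session_label": design.session_label,
        "tone_onset_s": tone_onsets,
    })
    ev_rows = []
    for k in range(nt):
        ev_rows.append((tone_onsets[k], "tone_onset", k + 1))
        for p in pip_onsets[k]:
            ev_rows.append((p, "pip_onset", k + 1))
        if us_onsets is not None:
            ev_rows.append((us_onsets[k], "us_onset", k + 1))
    events = pd.DataFrame(ev_rows, columns=["timestamp_s", "kind", "trial_index"])
    events = events.sort_values("timestamp_s", kind="stable").reset_index(drop=True)

    rec = SessionRecording(channels=channels, rate=rate, events=events,
                           trials=trials, animal_id=animal_id, group=group)
    truth = GroundTruth(
        session_label=design.session_label, seed=params.seed,
        lag=params.lag, coupling=params.coupling,
        theta_gain={r: gains[r].tolist() for r in REGIONS},
        aep_amplitude={r: aeps[r].tolist() for r in REGIONS},
        freeze_frac=None if freeze_frac is None else list(map(float, freeze_frac)),
    )
    return rec, truth


def simulate_coupled_pair(duration_s: float, params: SimulationParams,
                          seed: int | None = None):
    """Bare two-channel segment (shared/private theta + pink noise, no
    pips).  Used for estimator-calibration studies where the stimulus
    machinery would only add stimulus-locked common signal."""
    rate = params.sampling_rate
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(duration_s * rate))
    lag_samp = int(round(params.lag * rate))
    margin = abs(lag_samp) + 1
    shared = band_limited_noise(rng, n + 2 * margin, rate, params.theta_source_band)
    private = band_limited_noise(rng, n, rate, params.theta_source_band)
    c = params.coupling
    x = shared[margin:margin + n] * params.theta_sd
    y = (np.sqrt(c) * shared[margin - lag_samp:margin - lag_samp + n]
         + np.sqrt(1 - c) * private) * params.theta_sd
    if params.noise_sd > 0:
        x = x + pink_noise(rng, n, rate, params.band_limits,
                           params.pink_noise_exponent, params.noise_sd)
        y = y + pink_noise(rng, n, rate, params.band_limits,
                           params.pink_noise_exponent, params.noise_sd)
    return x, y


# ---------------------------------------------------------------------------
# freezing
# ---------------------------------------------------------------------------

def simulate_freezing(trial_freeze_fracs: Sequence[float],
                      tone_onsets: Sequence[float],
                      tone_duration: float = 30.0,
                      pretone_frac: float = 0.0,
                      seed: int | None = None,
                      deterministic: bool = False) -> pd.DataFrame:
    """Freezing intervals per trial plus the 30 s pretone window.

    Deterministic mode places a single bout of exactly
    ``frac * tone_duration`` seconds at each tone onset; stochastic mode
    freezes each 1 s slot of the window independently with probability
    ``frac`` (so the expected percent score is exactly 100*frac).
    Returns a DataFrame (trial_index, start_s, end_s); the pretone window
    is trial_index 0.
    """
    fracs = np.asarray(trial_freeze_fracs, dtype=float)
    if np.any((fracs < 0) | (fracs > 1)) or not 0 <= pretone_frac <= 1:
        raise ValueError("freezing fractions must lie in [0, 1]")
    if len(fracs) != len(tone_onsets):
        raise ValueError("one fraction per tone required")
    rng = np.random.default_rng(seed)
    rows = []

    def fill(idx: int, start: float, length: float, frac: float) -> None:
        if frac == 0:
            return
        if deterministic:
            rows.append((idx, start, start + frac * length))
            return
        slots = int(round(length))
        frozen = rng.random(slots) < frac
        i = 0
        while i < slots:
            if frozen[i]:
                j = i
                while j < slots and frozen[j]:
                    j += 1
                rows.append((idx, start + i, start + j))
                i = j
            else:
                i += 1

    first = float(tone_onsets[0])
    fill(0, first - 30.0, 30.0, pretone_frac)
    for k, onset in enumerate(tone_onsets):
        fill(k + 1, float(onset), tone_duration, fracs[k])
    return pd.DataFrame(rows, columns=["trial_index", "start_s", "end_s"])
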