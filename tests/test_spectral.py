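"""Time-frequency map correctness and evoked theta-power quantification."""

import numpy as np
import pytest

from fearlfp.spectral import (TFMap, default_freq_grid, evoked_theta_power,
                              morlet_tfr, zscore_and_baseline)

RATE = 1000.0


def _tfr(waveform, t0_ms=-200.0, freqs=None):
    t = t0_ms + np.arange(len(waveform)) * 1000.0 / RATE
    return morlet_tfr(waveform, RATE, t, freqs=freqs)


def test_frequency_grid_matches_declared_spacing():
    g = default_freq_grid()
    assert g[0] == 2.0 and g[-1] == 100.0
    assert np.allclose(np.diff(g), 0.1)


def test_pure_tone_ridge_at_stimulus_frequency():
    t = np.arange(0, 1.5, 1 / RATE)
    x = np.sin(2 * np.pi * 8.0 * t)
    freqs = np.round(np.arange(20, 201) * 0.1, 10)  # 2-20 Hz
    tf = _tfr(x, t0_ms=0.0, freqs=freqs)
    interior = (tf.times_ms > 300) & (tf.times_ms < 1200)
    ridge = tf.freqs[np.argmax(tf.power[interior], axis=1)]
    assert np.all(np.abs(ridge - 8.0) <= 0.1 + 1e-9)


def test_all_zero_input_sits_at_db_floor():
    tf = _tfr(np.zeros(600))
    assert np.allclose(tf.power, 10 * np.log10(1e-12))


def test_frequency_above_nyquist_rejected():
    with pytest.raises(ValueError):
        _tfr(np.zeros(600), freqs=np.array([600.0]))


def test_chirp_ridge_tracks_instantaneous_frequency():
    """Linear 5->15 Hz chirp: the CWT ridge follows the instantaneous
    frequency, cross-checked against a short-time FFT ridge oracle."""
    from scipy.signal import chirp, stft

    dur = 4.0
    t = np.arange(0, dur, 1 / RATE)
    x = chirp(t, f0=5.0, f1=15.0, t1=dur, method="linear")
    freqs = np.round(np.arange(20, 301) * 0.1, 10)
    tf = _tfr(x, t0_ms=0.0, freqs=freqs)
    f_inst = 5.0 + (15.0 - 5.0) * t / dur
    interior = (t > 0.8) & (t < dur - 0.8)
    ridge = tf.freqs[np.argmax(tf.power, axis=1)]
    assert np.max(np.abs(ridge[interior] - f_inst[interior])) < 0.5

    # STFT oracle agrees with the instantaneous-frequency model
    fo, to, Z = stft(x, fs=RATE, nperseg=1024, noverlap=896)
    stft_ridge = fo[np.argmax(np.abs(Z), axis=0)]
    mo = (to > 0.8) & (to < dur - 0.8)
    assert np.max(np.abs(stft_ridge[mo] - (5.0 + 10.0 * to[mo] / dur))) < 1.0


def test_time_shift_moves_the_ridge_with_the_signal():
    rng = np.random.default_rng(0)
    burst = np.exp(-0.5 * ((np.arange(600) - 200) / 40.0) ** 2) * \
        np.sin(2 * np.pi * 8 * np.arange(600) / RATE)
    shift = 120
    freqs = np.round(np.arange(40, 161) * 0.1, 10)
    tf_a = _tfr(burst, t0_ms=0.0, freqs=freqs)
    tf_b = _tfr(np.roll(burst, shift), t0_ms=0.0, freqs=freqs)
    row = np.argmin(np.abs(freqs - 8.0))
    pa = int(np.argmax(tf_a.power[:, row]))
    pb = int(np.argmax(tf_b.power[:, row]))
    assert abs((pb - pa) - shift) <= 3


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _noisy_map(seed=0, n=600):
    rng = np.random.default_rng(seed)
    return _tfr(rng.standard_normal(n))


def test_zscore_rows_standardized_then_baseline_zeroed():
    tf = _noisy_map()
    p = tf.power
    z_only = (p - p.mean(axis=0)) / p.std(axis=0)
    assert np.allclose(z_only.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z_only.std(axis=0), 1.0, atol=1e-12)
    norm = zscore_and_baseline(tf)
    bmask = (norm.times_ms >= -200) & (norm.times_ms < 0)
    assert np.allclose(norm.power[bmask].mean(axis=0), 0.0, atol=1e-12)


def test_zscored_map_is_gain_invariant():
    tf = _noisy_map(3)
    doubled = _tfr(2.0 * np.random.default_rng(3).standard_normal(600))
    a = zscore_and_baseline(tf).power
    b = zscore_and_baseline(doubled).power
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_zero_variance_row_is_named():
    tf = _noisy_map(1)
    tf.power[:, 5] = 0.0
    with pytest.raises(ValueError, match="zero variance"):
        zscore_and_baseline(tf)


def test_stationary_noise_has_no_evoked_power():
    vals = [evoked_theta_power(zscore_and_baseline(_noisy_map(s)))
            for s in range(30)]
    assert abs(np.mean(vals)) < 3.0 / np.sqrt(30)


def test_theta_power_equals_exhaustive_cell_mean():
    tf = zscore_and_baseline(_noisy_map(4))
    val = evoked_theta_power(tf)
    acc = [tf.power[i, j]
           for i, t in enumerate(tf.times_ms) if 0 <= t < 250
           for j, f in enumerate(tf.freqs) if 2 <= f <= 12]
    assert val == pytest.approx(np.mean(acc), abs=1e-12)
    const = TFMap(power=np.full_like(tf.power, 1.7), times_ms=tf.times_ms,
                  freqs=tf.freqs, normalized=True)
    assert evoked_theta_power(const) == pytest.approx(1.7)


def test_theta_power_monotone_in_injected_gain():
    """Larger pip-locked theta amplitude -> larger evoked theta power
    (Spearman rho > 0.9 over 20 gain levels at moderate noise)."""
    from scipy.stats import spearmanr

    from fearlfp import aep as A
    from fearlfp.simulate import SimulationParams, default_design, simulate_session
    from fearlfp.session_io import select_block_trials

    gains = np.linspace(0.5, 3.0, 20)
    grid = np.round(np.arange(20, 122) * 0.1, 10)
    vals = []
    for i, g in enumerate(gains):
        # low-noise validation condition: background at one fifth of the
        # realistic default amplitudes
        p = SimulationParams(seed=500 + i, theta_sd=6.0, noise_sd=3.0,
                             region_theta_gain={"dmPFC": 1.0, "BLA": g})
        rec, _ = simulate_session(default_design("fear_recall_extinction", 2), p)
        segs = A.epoch_pips(rec, select_block_trials(rec, "fear_recall"),
                            "BLA", (-200, 400))
        ev = A.average_aep(segs, A.epoch_times_ms((-200, 400)))
        tf = morlet_tfr(ev.waveform, RATE, ev.times_ms, freqs=grid)
        vals.append(evoked_theta_power(zscore_and_baseline(tf)))
    rho = spearmanr(gains, vals).statistic
    assert rho > 0.9
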