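"""Coherence, envelope extraction, lagged correlation, surrogate null."""

import numpy as np
import pytest

from fearlfp.connectivity import (coherence_spectrum, cs_window_segments,
                                  envelope_xcorr, lead_lag, surrogate_peaks,
                                  theta_envelope, _histogram_mode)
from fearlfp.simulate import SimulationParams, simulate_coupled_pair

RATE = 1000.0


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def test_identical_channels_fully_coherent():
    x = np.random.default_rng(0).standard_normal(8000)
    c = coherence_spectrum(x, x, RATE)
    assert np.all(c.coherence > 1 - 1e-6)
    assert c.theta_summary == pytest.approx(1.0, abs=1e-6)


def test_pure_delay_preserves_coherence():
    x = np.random.default_rng(1).standard_normal(30000)
    y = np.roll(x, 10)  # 10 ms delay
    c = coherence_spectrum(x, y, RATE)
    theta = c.coherence[(c.freqs >= 2) & (c.freqs <= 12)]
    assert theta.mean() > 0.95


def test_uncoupled_pairs_sit_at_finite_sample_floor():
    """Independent noise: theta coherence matches the Monte-Carlo floor
    for the same segment count (oracle: 200 independent replicate pairs)."""
    rng = np.random.default_rng(2)
    n = 30000
    floor = [coherence_spectrum(rng.standard_normal(n), rng.standard_normal(n),
                                RATE).theta_summary for _ in range(200)]
    mu, sd = np.mean(floor), np.std(floor)
    x = np.random.default_rng(77).standard_normal(n)
    y = np.random.default_rng(78).standard_normal(n)
    val = coherence_spectrum(x, y, RATE).theta_summary
    assert abs(val - mu) < 4 * sd
    # the floor is well below any genuine coupling signal
    assert mu < 0.3


def test_coherence_monotone_in_coupling():
    vals = []
    for c in (0.0, 0.3, 0.6, 0.9):
        p = SimulationParams(coupling=c, lag=0.0, seed=5)
        acc = [coherence_spectrum(*simulate_coupled_pair(30.0, p, seed=100 * s + int(10 * c)),
                                  RATE).theta_summary for s in range(5)]
        vals.append(np.mean(acc))
    assert vals == sorted(vals)


def test_short_segment_rejected():
    with pytest.raises(ValueError):
        coherence_spectrum(np.zeros(100), np.zeros(100), RATE)


def test_coherence_invariant_to_channel_gain():
    p = SimulationParams(coupling=0.6, seed=8)
    x, y = simulate_coupled_pair(30.0, p)
    a = coherence_spectrum(x, y, RATE).theta_summary
    b = coherence_spectrum(3.7 * x, 0.2 * y, RATE).theta_summary
    assert a == pytest.approx(b, rel=1e-9)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def test_pure_tone_envelope_is_flat_and_demeaned():
    t = np.arange(0, 10, 1 / RATE)
    x = 3.0 * np.sin(2 * np.pi * 8 * t)
    env = theta_envelope(x, RATE)
    interior = env[2000:-2000]
    assert np.max(np.abs(interior)) < 0.02 * 3.0  # ~A before demeaning, ~0 after


def test_envelope_tracks_slow_amplitude_modulation():
    t = np.arange(0, 20, 1 / RATE)
    am = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
    x = am * np.sin(2 * np.pi * 8 * t)
    env = theta_envelope(x, RATE)            # demeaned instantaneous amplitude
    recon = env + am.mean()                  # undo demeaning with the known mean
    interior = slice(3000, -3000)
    assert np.max(np.abs(recon[interior] - am[interior])) < 0.05 * am.max()


def test_zero_signal_gives_zero_envelope():
    assert np.allclose(theta_envelope(np.zeros(5000), RATE), 0.0)


# ---------------------------------------------------------------------------
# lagged correlation
# ---------------------------------------------------------------------------

def _ar1(rng, n, phi=0.99):
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.standard_normal()
    return x


def test_xcorr_identity_and_known_delay():
    rng = np.random.default_rng(3)
    e = _ar1(rng, 5000)
    _, _, pl, pv = envelope_xcorr(e, e, RATE)
    assert pl == 0.0 and pv == pytest.approx(1.0)
    _, _, pl, _ = envelope_xcorr(e, np.roll(e, 20), RATE)
    assert pl == pytest.approx(0.020, abs=1.5e-3)


def test_xcorr_matches_brute_force_pearson_oracle():
    rng = np.random.default_rng(4)
    a, b = _ar1(rng, 1200), _ar1(rng, 1200)
    lags, r, _, _ = envelope_xcorr(a, b, RATE, max_lag=0.05)
    n = a.size
    for k, lag in [(-50, 0), (-7, 0), (0, 0), (13, 0), (50, 0)]:
        if k >= 0:
            expect = np.corrcoef(a[:n - k], b[k:])[0, 1] if k else np.corrcoef(a, b)[0, 1]
        else:
            expect = np.corrcoef(a[-k:], b[:n + k])[0, 1]
        assert r[np.argmin(np.abs(lags - k / RATE))] == pytest.approx(expect, abs=1e-10)


def test_xcorr_errors():
    with pytest.raises(ValueError):
        envelope_xcorr(np.zeros(100), np.ones(100), RATE, max_lag=0.01)
    with pytest.raises(ValueError):
        envelope_xcorr(np.arange(50.0), np.arange(50.0), RATE, max_lag=0.1)


# ---------------------------------------------------------------------------
# surrogates and lead/lag summary
# ---------------------------------------------------------------------------

def test_strong_delayed_coupling_beats_all_surrogates():
    rng = np.random.default_rng(5)
    e = _ar1(rng, 30000)
    shifted = np.roll(e, 20)
    peaks = surrogate_peaks(e, shifted, RATE, n=100, rng=1)
    _, _, _, actual = envelope_xcorr(e, shifted, RATE)
    assert np.all(actual > peaks)
    with pytest.raises(ValueError):
        surrogate_peaks(e, shifted, RATE, n=0)
    with pytest.raises(ValueError):
        surrogate_peaks(e[:5000], shifted[:5000], RATE, n=10)  # too short


def test_lead_lag_summary_and_significance():
    rng = np.random.default_rng(6)
    segs = []
    for _ in range(4):
        e = _ar1(rng, 30000)
        segs.append((e, np.roll(e, 20)))
    res = lead_lag(segs, RATE, n_surrogates=25, seed=0)
    assert res.summary_lag == pytest.approx(0.020, abs=5e-3)
    assert res.significant
    assert res.surrogate_peaks.size == 4 * 25
    assert res.exceedance_fraction() > 0.95


def test_lead_lag_antisymmetric_under_channel_swap():
    p = SimulationParams(coupling=0.9, lag=0.02, seed=11)
    x, y = simulate_coupled_pair(30.0, p)
    ea, eb = theta_envelope(x, RATE), theta_envelope(y, RATE)
    fwd = lead_lag([(ea, eb)], RATE, n_surrogates=5, seed=1)
    rev = lead_lag([(eb, ea)], RATE, n_surrogates=5, seed=1)
    assert fwd.peak_lags[0] == -rev.peak_lags[0]
    assert fwd.summary_lag == -rev.summary_lag


def test_lead_lag_invariant_to_channel_gain():
    p = SimulationParams(coupling=0.9, lag=-0.05, seed=12)
    x, y = simulate_coupled_pair(30.0, p)
    ea, eb = theta_envelope(x, RATE), theta_envelope(y, RATE)
    a = lead_lag([(ea, eb)], RATE, n_surrogates=5, seed=2)
    b = lead_lag([(5.0 * ea, 0.3 * eb)], RATE, n_surrogates=5, seed=2)
    assert a.peak_lags[0] == b.peak_lags[0]
    assert a.peak_values[0] == pytest.approx(b.peak_values[0], rel=1e-9)


def test_histogram_mode_tie_breaks_toward_zero():
    assert _histogram_mode(np.array([0.02, 0.02, -0.05]), 0.1, 0.005) == 0.02
    # tie between 0.04 and 0.01 -> smaller |center| wins
    assert _histogram_mode(np.array([0.04, 0.01]), 0.1, 0.005) == 0.01


def test_recovers_injected_lag_through_full_stack(small_session):
    rec, truth = small_session  # coupling 0.9, lag +20 ms
    segs = cs_window_segments(rec, [1, 2])
    res = lead_lag(segs, rec.rate, n_surrogates=50, seed=3)
    assert abs(res.summary_lag - truth.lag) <= 0.005 + 1e-12
    assert res.significant


@pytest.mark.parametrize("lag_ms", [-20.0, 20.0])
def test_median_lag_recovery_at_moderate_coupling(lag_ms):
    """Median recovered lag stays within one 5 ms bin of truth down to
    coupling 0.7."""
    from fearlfp.simulate import default_design, simulate_session
    from fearlfp.session_io import select_block_trials

    recovered = []
    for s in range(6):
        p = SimulationParams(seed=9000 + s, coupling=0.7, lag=lag_ms / 1000.0)
        rec, _ = simulate_session(default_design("fear_recall_extinction", 2), p)
        tr = select_block_trials(rec, "fear_recall")
        res = lead_lag(cs_window_segments(rec, tr), rec.rate,
                       n_surrogates=5, seed=s)
        recovered.append(res.summary_lag)
    assert abs(np.median(recovered) - lag_ms / 1000.0) <= 0.005 + 1e-12
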