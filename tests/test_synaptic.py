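"""Unitary transmission and spontaneous-event estimators."""

import numpy as np
import pytest

from pvint.core import InsufficientDataError, PairedRecording, Trace
from pvint.synaptic import (
    connection_probability,
    detect_sepsc,
    train_dynamics,
    unitary_stats,
)
from pvint.synth import PairSpec, simulate_pair, train_50hz

DT = 0.05


def _square_response_pair(amplitudes, ap_time=20.0, dur=60.0):
    """One AP per trial; trial k shows a clean rectangular inward current
    of the given magnitude (0 = failure)."""
    n = int(dur / DT)
    j = int(ap_time / DT)
    trials = np.zeros((len(amplitudes), n))
    for k, a in enumerate(amplitudes):
        trials[k, j + 20:j + 80] = -a   # 1-4 ms after the AP peak
    return PairedRecording(dt_ms=DT, ap_times_ms=[ap_time], trials=trials)


def test_unitary_formulas_with_failures():
    """10 trials, 2 failures, successes all 60 pA: potency 60, amplitude
    48, failure probability 0.2."""
    pair = _square_response_pair([60.0] * 8 + [0.0] * 2)
    s = unitary_stats(pair)
    assert s.potency == pytest.approx(60.0)
    assert s.amplitude == pytest.approx(48.0)
    assert s.failure_probability == pytest.approx(0.2)
    assert s.n_events == 10


def test_all_failures():
    s = unitary_stats(_square_response_pair([0.0] * 10))
    assert s.potency is None
    assert s.failure_probability == 1.0


def test_latency_is_five_percent_crossing_exact():
    spec = PairSpec(p0=1.0, U=0.0, noise_sd_pA=0.0, jitter_ms=0.0,
                    latency_ms=1.2)
    pair = simulate_pair(spec, [20.0], n_trials=10, seed=0)
    s = unitary_stats(pair)
    assert s.latency == pytest.approx(1.2, abs=DT)


def test_potency_never_below_amplitude():
    for seed in range(10):
        spec = PairSpec(p0=0.7, potency_pA=60.0, noise_sd_pA=2.0)
        s = unitary_stats(simulate_pair(spec, [20.0], n_trials=40, seed=seed))
        assert s.potency >= s.amplitude
    # equality exactly when nothing fails
    s = unitary_stats(_square_response_pair([60.0] * 10))
    assert s.potency == pytest.approx(s.amplitude)
    assert s.failure_probability == 0.0


def test_wt_fs_basket_preset_recovery():
    """Estimators recover the published basket-cell connection profile:
    near-zero failures, about 1.2 ms latency, about 6.6 ms decay."""
    from pvint.synth import PAIR_TABLE

    pair = simulate_pair(PAIR_TABLE["WT_FS_BC"], [20.0], n_trials=200, seed=3)
    s = unitary_stats(pair)
    assert s.failure_probability == pytest.approx(0.01, abs=0.05)
    assert s.latency == pytest.approx(1.2, abs=0.2)
    assert s.decay_tau == pytest.approx(6.6, abs=1.0)
    assert s.potency == pytest.approx(171.0, rel=0.1)


def test_train_no_depression_when_u_zero():
    spec = PairSpec(p0=1.0, U=0.0, noise_sd_pA=0.0, jitter_ms=0.0)
    td = train_dynamics(simulate_pair(spec, train_50hz(), n_trials=5, seed=0))
    # residual temporal summation at 50 Hz biases a peak-minus-baseline
    # estimator by a couple of percent even without depression
    assert td.end_depression == pytest.approx(0.0, abs=0.03)
    assert td.end_failure_rate == 0.0
    assert td.pulse_amplitude[0] == 1.0


def test_train_end_depression_arithmetic():
    """Deterministic amplitudes 100 then 30 on the last five pulses give
    exactly 70% end-of-train depression."""
    n = int((train_50hz()[-1] + 60) / DT)
    amps = np.r_[[100.0], np.linspace(90, 35, 19), [30.0] * 5]
    trials = np.zeros((5, n))
    for t_ap, a in zip(train_50hz(), amps):
        j = int(t_ap / DT)
        trials[:, j + 20:j + 80] = -a
    pair = PairedRecording(dt_ms=DT, ap_times_ms=train_50hz(), trials=trials)
    td = train_dynamics(pair)
    assert td.end_depression == pytest.approx(0.70)
    assert td.pulse_amplitude[0] == 1.0


def test_train_recovers_designed_failure_rate():
    spec = PairSpec(p0=0.99, potency_pA=171.0)  # tuned to ~0.29 end failures
    td = train_dynamics(simulate_pair(spec, train_50hz(), n_trials=20, seed=9))
    assert td.end_failure_rate == pytest.approx(0.29, abs=0.08)
    assert td.end_depression == pytest.approx(0.70, abs=0.08)


def test_train_validation():
    spec = PairSpec()
    with pytest.raises(ValueError, match="pulses"):
        train_dynamics(simulate_pair(spec, train_50hz(10), n_trials=5, seed=0))
    with pytest.raises(InsufficientDataError, match="trials"):
        train_dynamics(simulate_pair(spec, train_50hz(), n_trials=2, seed=0))


# -- spontaneous events -----------------------------------------------------

def _sepsc_trace(event_times_ms, amp=30.0, dur_s=10.0, noise=3.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur_s * 1000 / DT)
    i = rng.normal(0, noise, n)
    t = np.arange(0, 40, DT)
    kern = np.exp(-t / 4.0) - np.exp(-t / 0.4)
    kern /= kern.max()
    for t0 in event_times_ms:
        j = int(t0 / DT)
        m = min(len(kern), n - j)
        i[j:j + m] -= amp * kern[:m]
    return Trace(time_step=DT, voltage=np.full(n, -70.0), current=i,
                 protocol_tag="continuous")


def test_sepsc_detection_rate_and_frequency():
    times = np.sort(np.random.default_rng(1).uniform(100, 9900, 100) * 1.0)
    times = times[np.r_[True, np.diff(times) > 20]]
    tr = _sepsc_trace(times)
    events, stats = detect_sepsc(tr)
    assert stats.n_events >= 0.98 * len(times)
    expected_hz = len(times) / 10.0
    assert stats.frequency == pytest.approx(expected_hz, rel=0.05)
    assert stats.mean_amplitude == pytest.approx(30.0, rel=0.2)
    assert stats.sufficient


def test_sepsc_false_positive_rate_on_noise():
    for seed in range(3):
        tr = _sepsc_trace([], seed=seed)
        _, stats = detect_sepsc(tr)
        assert stats.n_events <= 2
        assert not stats.sufficient


def test_sepsc_needs_duration():
    with pytest.raises(InsufficientDataError):
        detect_sepsc(Trace(time_step=DT, voltage=np.zeros(100),
                           current=np.zeros(100), protocol_tag="continuous"))


# -- connectivity -----------------------------------------------------------

def test_connection_probability_published_ratios():
    frac, _ = connection_probability(41, 11)
    assert frac * 100 == pytest.approx(26.8, abs=0.1)
    frac, _ = connection_probability(30, 8)
    assert frac * 100 == pytest.approx(26.7, abs=0.1)
    frac, (lo, hi) = connection_probability(3, 0)
    assert frac == 0.0 and lo == 0.0
    assert hi == pytest.approx(0.7076, abs=1e-3)  # closed-form Clopper-Pearson
    with pytest.raises(ValueError):
        connection_probability(0, 0)
    with pytest.raises(ValueError):
        connection_probability(5, 6)
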