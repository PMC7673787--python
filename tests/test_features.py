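"""Feature extraction against analytic constructions and generator designs."""

import numpy as np
import pytest

from pvint.core import InsufficientDataError, Trace
from pvint.features import (
    block_current,
    capacitance,
    classify_block_in_continuous,
    detect_spikes,
    extract_all,
    firing_frequency,
    input_resistance,
    membrane_time_constant,
    rheobase,
    sag_index,
)
from pvint.synth import SynthCellSpec, simulate_cell, simulate_elevated_k

from conftest import DT, make_step_trace, simple_spike_train


# -- spike detection --------------------------------------------------------

def test_no_spikes_on_flat_trace():
    tr = make_step_trace(np.full(14_000, -65.0), 100.0)
    assert detect_spikes(tr) == []


def test_triangular_pulse_threshold_at_slope_criterion():
    """A 20 mV/ms triangular rise from -60 to 0 mV: one spike whose
    threshold sits at the first sample with dV/dt >= 10 mV/ms."""
    n = 14_000
    v = np.full(n, -60.0)
    j0 = 7000
    rise = np.arange(0, 3.0, DT) * 20.0         # 3 ms up at 20 mV/ms
    fall = 0.0 - np.arange(0, 3.0, DT) * 20.0   # back down
    v[j0:j0 + len(rise)] = -60.0 + rise
    v[j0 + len(rise):j0 + len(rise) + len(fall)] = fall
    tr = make_step_trace(v, 400.0)
    ev = detect_spikes(tr)
    assert len(ev) == 1
    # constant 20 mV/ms slope: the rising phase of >= 10 mV/ms starts at
    # the ramp base, so the threshold is the base voltage
    assert ev[0].threshold_V == pytest.approx(-60.0, abs=1.0)
    assert ev[0].peak_V == pytest.approx(0.0, abs=0.5)


def test_designed_half_width_recovered(fs_recording, fs_spec):
    f = extract_all(fs_recording)
    assert f.ap_halfwidth == pytest.approx(fs_spec.ap_halfwidth, abs=0.05)


def test_waveform_metrics_on_designed_spike(fs_recording, fs_spec):
    f = extract_all(fs_recording)
    assert f.ap_threshold == pytest.approx(fs_spec.ap_threshold, abs=1.0)
    assert f.ap_amplitude == pytest.approx(fs_spec.ap_amplitude, rel=0.03)
    assert f.ahp_amplitude == pytest.approx(fs_spec.ahp, abs=1.0)
    assert f.max_rise == pytest.approx(fs_spec.max_rise, rel=0.12)
    assert f.max_decay == pytest.approx(fs_spec.max_decay, rel=0.12)


# -- passive properties -----------------------------------------------------

def _rc_sweeps(rin_mohm=100.0, tau=10.0, vrest=-65.0,
               amps=(-200, -150, -100, -50, 0, 50)):
    sweeps = []
    for amp in amps:
        n = 14_000
        a, b = 2000, 12_000
        v = np.full(n, vrest)
        t = (np.arange(a, b) - a) * DT
        dv = rin_mohm * amp / 1000.0
        v[a:b] += dv * (1 - np.exp(-t / tau))
        v[b:] = v[b - 1]
        sweeps.append(make_step_trace(v, float(amp), tag="subthreshold_steps"))
    return sweeps


def test_input_resistance_exact_on_rc():
    assert input_resistance(_rc_sweeps(100.0)) == pytest.approx(100.0, rel=1e-3)


def test_input_resistance_zero_deflection():
    assert input_resistance(_rc_sweeps(0.0)) == pytest.approx(0.0, abs=1e-9)


def test_input_resistance_needs_two_sweeps():
    with pytest.raises(InsufficientDataError):
        input_resistance(_rc_sweeps(100.0)[:1])


def test_time_constant_exact_exponential():
    pulses = _rc_sweeps(100.0, tau=10.0, amps=[-20] * 6)
    assert membrane_time_constant(pulses) == pytest.approx(10.0, abs=0.1)


def test_time_constant_bias_under_slow_sag():
    """With a slow (tau >= 100 ms) sag component superposed, the restricted
    fit window keeps the bias under 10% for tau_m <= 15 ms."""
    for tau_m in (8.5, 15.0):
        sweeps = []
        for _ in range(6):
            n = 12_000
            a, b = 2000, 10_000
            v = np.full(n, -65.0)
            t = (np.arange(a, b) - a) * DT
            dv = -2.0
            v[a:b] += (dv / 0.9) * (1 - np.exp(-t / tau_m)) \
                + (dv - dv / 0.9) * (1 - np.exp(-t / 120.0))
            sweeps.append(make_step_trace(v, -20.0, step_ms=400.0,
                                          tag="tau_pulses"))
        est = membrane_time_constant(sweeps)
        assert est == pytest.approx(tau_m, rel=0.10)


def test_capacitance_arithmetic():
    assert capacitance(100.0, 10.0) == pytest.approx(100.0)
    assert capacitance(82.5, 8.5) == pytest.approx(103.0, abs=0.1)
    with pytest.raises(ValueError):
        capacitance(100.0, 0.0)


# -- firing properties ------------------------------------------------------

def test_rheobase_first_spiking_step():
    quiet = make_step_trace(np.full(14_000, -65.0), 300.0, sweep_id="a")
    spiking = simple_spike_train([300.0, 400.0])
    spiking.meta["step_pA"] = 350.0
    assert rheobase([quiet, spiking]) == 350.0
    spiking.meta["step_pA"] = 50.0
    assert rheobase([spiking, quiet]) == 50.0
    assert rheobase([quiet]) is None


def test_firing_frequency_and_adaptation_formulas():
    # 20 evenly spaced spikes within the 500 ms step: 40 Hz, AR = 1
    times = 110.0 + 25.0 * np.arange(20)
    tr = simple_spike_train(times)
    tr.meta["step_pA"] = 400.0
    ff, ar = firing_frequency([tr], 200.0, 2)
    assert ff == pytest.approx(40.0)
    assert ar == pytest.approx(1.0, abs=0.01)

    # ISIs [10,10,10,20,20,20] -> AR = 2; [10,10,10,8,8,8] -> AR = 0.8
    for isis, expect in [([10, 10, 10, 20, 20, 20], 2.0),
                         ([10, 10, 10, 8, 8, 8], 0.8)]:
        times = 120.0 + np.concatenate([[0.0], np.cumsum(isis)])
        tr = simple_spike_train(times)
        tr.meta["step_pA"] = 400.0
        _, ar = firing_frequency([tr], 200.0, 2)
        assert ar == pytest.approx(expect, abs=0.02)


def test_adaptation_null_below_seven_spikes():
    tr = simple_spike_train(110.0 + 30.0 * np.arange(5))
    tr.meta["step_pA"] = 400.0
    ff, ar = firing_frequency([tr], 200.0, 2)
    assert ff == pytest.approx(10.0)
    assert ar is None


# -- sag --------------------------------------------------------------------

def test_sag_formula_cases():
    def sweep(vhyp, vsag, amp):
        n = 14_000
        a, b = 2000, 12_000
        v = np.full(n, -65.0)
        v[a:a + 2000] = vhyp           # early trough
        v[a + 2000:b] = vsag           # steady plateau
        return make_step_trace(v, amp, tag="subthreshold_steps")

    assert sag_index([sweep(-85.0, -80.0, -200.0)], -65.0) == \
        pytest.approx(0.75, abs=0.01)
    assert sag_index([sweep(-80.0, -80.0, -200.0)], -65.0) == \
        pytest.approx(1.0, abs=0.01)
    with pytest.raises(InsufficientDataError):
        sag_index([sweep(-80.0, -80.0, 50.0)], -65.0)


def test_sag_selects_sweep_nearest_minus_80(nfs_recording, nfs_spec):
    s = sag_index(nfs_recording.by_protocol("subthreshold_steps"))
    assert s == pytest.approx(nfs_spec.sag, abs=0.03)


# -- depolarization block ---------------------------------------------------

def test_block_censored_when_spiking_throughout(fs_recording):
    f = extract_all(fs_recording)
    assert f.block_current is None
    assert f.entered_block is False


def test_block_criterion_on_constructed_plateau():
    """Spikes cease at 200 of 500 ms with a -30 mV plateau: blocked."""
    tr = simple_spike_train(110.0 + 10.0 * np.arange(19))  # last at 290 ms
    a, b = 2000, 12_000
    j = int(round(310.0 / DT))
    tr.voltage[j:b] = -30.0
    tr.meta["step_pA"] = 700.0
    full = simple_spike_train(110.0 + 10.0 * np.arange(48))
    full.meta["step_pA"] = 650.0
    amp, entered = block_current([full, tr], ap_threshold=-40.0)
    assert (amp, entered) == (700.0, True)


def test_block_detected_at_designed_current(nfs_recording, nfs_spec):
    f = extract_all(nfs_recording)
    assert f.entered_block is True
    assert f.block_current == pytest.approx(nfs_spec.block_current, abs=100.0)


def test_continuous_block_classification():
    fs = SynthCellSpec(seed=3, noise_v=0.2)
    sweeps = simulate_elevated_k(fs, n_sweeps=4, sweep_s=2.0, seed=3)
    assert classify_block_in_continuous(sweeps, fs.ap_threshold,
                                        skip_first_s=2.0) is False
    blocker = SynthCellSpec(seed=4, rheobase=200.0, block_current=300.0)
    sweeps = simulate_elevated_k(blocker, n_sweeps=4, sweep_s=2.0,
                                 block_after_sweep=2, seed=4)
    assert classify_block_in_continuous(sweeps, blocker.ap_threshold,
                                        skip_first_s=2.0) is True
    with pytest.raises(InsufficientDataError):
        classify_block_in_continuous(
            [make_step_trace(np.full(1000, -65.0), 0.0, tag="continuous")],
            -40.0)


# -- aggregation ------------------------------------------------------------

def test_extract_all_complete_cell(fs_recording):
    f = extract_all(fs_recording)
    for name in ("rin", "tau_m", "cm", "rheobase", "ap_threshold",
                 "ap_amplitude", "ap_halfwidth", "ahp_amplitude",
                 "max_rise", "max_decay", "ff_2x", "ff_3x", "ar_2x",
                 "ar_3x", "sag_index"):
        assert getattr(f, name) is not None, name
    assert f.nulls == {}


def test_extract_all_missing_protocol_goes_null(fs_spec):
    rec = simulate_cell(fs_spec)
    rec.sweeps = [s for s in rec.sweeps if s.protocol_tag != "tau_pulses"]
    f = extract_all(rec)
    assert f.tau_m is None and "tau_m" in f.nulls
    assert f.cm is None
    assert f.rin is not None and f.ff_2x is not None


def test_extract_all_deterministic(fs_recording):
    f1 = extract_all(fs_recording)
    f2 = extract_all(fs_recording)
    assert f1.to_dict() == f2.to_dict()
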