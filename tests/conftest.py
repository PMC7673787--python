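import numpy as np
import pytest

from pvint.core import DEFAULT_DT_MS, CellRecording, StepProtocol, Trace
from pvint.synth import SynthCellSpec, simulate_cell

DT = DEFAULT_DT_MS


def make_step_trace(voltage, step_pA, baseline_ms=100.0, step_ms=500.0,
                    tag="firing_steps", dt=DT, sweep_id="s0"):
    """Wrap a voltage array in a Trace with step metadata."""
    v = np.asarray(voltage, dtype=float)
    n = len(v)
    cur = np.zeros(n)
    a = int(round(baseline_ms / dt))
    b = int(round((baseline_ms + step_ms) / dt))
    cur[a:b] = step_pA
    return Trace(time_step=dt, voltage=v, current=cur, sweep_id=sweep_id,
                 protocol_tag=tag,
                 meta={"step_pA": step_pA, "baseline_ms": baseline_ms,
                       "step_ms": step_ms})


def simple_spike_train(spike_times_ms, total_ms=700.0, baseline_ms=100.0,
                       step_ms=500.0, v_rest=-65.0, v_thr=-40.0,
                       v_peak=10.0, dt=DT):
    """Trace with triangular spikes (20 mV/ms rise, -25 mV/ms fall) at the
    given times (ms, absolute).  Slopes far exceed the 10 mV/ms threshold
    criterion, so every spike is detected with threshold near v_thr."""
    n = int(round(total_ms / dt))
    v = np.full(n, v_rest)
    rise = (v_peak - v_thr) / 20.0   # ms
    fall = (v_peak - v_thr) / 25.0
    for t0 in spike_times_ms:
        # slow approach ramp so detection anchors at the triangle base
        ramp = np.arange(-2.0, 0, dt)
        for tt, vv in zip(ramp, v_thr - 4.0 + (ramp + 2.0) * 2.0):
            j = int(round((t0 + tt) / dt))
            if 0 <= j < n:
                v[j] = max(v[j], vv)
        for tt in np.arange(0, rise + fall, dt):
            j = int(round((t0 + tt) / dt))
            if 0 <= j < n:
                v[j] = (v_thr + 20.0 * tt if tt < rise
                        else v_peak - 25.0 * (tt - rise))
    return make_step_trace(v, 400.0, baseline_ms, step_ms)


@pytest.fixture(scope="session")
def fs_spec():
    """A wild-type fast-spiking cell at the published feature means."""
    return SynthCellSpec(seed=42)


@pytest.fixture(scope="session")
def fs_recording(fs_spec):
    return simulate_cell(fs_spec)


@pytest.fixture(scope="session")
def nfs_spec():
    return SynthCellSpec(
        cell_id="nfs", seed=7, rin=143.1, tau_m=10.9, rheobase=150.0,
        ap_threshold=-40.6, ap_amplitude=65.4, ap_halfwidth=0.59,
        ahp=-15.7, max_rise=228.6, max_decay=-136.5, ff2x=66.0, ff3x=96.1,
        ar2x=0.67, ar3x=0.65, sag=0.80, block_current=700.0)


@pytest.fixture(scope="session")
def nfs_recording(nfs_spec):
    return simulate_cell(nfs_spec)
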