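"""Spontaneous EPSC statistics and unitary IPSC transmission analysis.

Sign convention: with a high-chloride internal solution, GABAergic
currents recorded at -70 mV are inward (negative deflections).  All
amplitudes are reported as positive magnitudes.

Definitions
-----------
* potency: mean peak response over successful trials only.
* amplitude: mean over *all* trials, counting failures as zero, so
  amplitude = potency * (1 - failure probability) and potency >= amplitude
  always, with equality exactly when nothing fails.
* failure: a trial whose response peak stays below ``fail_k`` baseline
  SDs (default 3) in the response window (0.5-8 ms after the AP peak).
* latency: time from the presynaptic AP peak to the first crossing of 5%
  of the potency, averaged over successes.
* train dynamics: per-pulse amplitudes (failures as zero) averaged over
  trials and normalized to pulse 1; "end of train" = pulses 21-25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import beta

from .core import InsufficientDataError, PairedRecording, Trace

#: response search window after the presynaptic AP peak, ms
RESPONSE_WINDOW_MS = (0.5, 8.0)
#: failure criterion: peak below this many baseline SDs
FAIL_K_SD = 3.0
#: baseline window before each AP used for local baseline / SD, ms
BASELINE_MS = 5.0


@dataclass
class DetectedEvent:
    onset_time: float
    peak_amplitude: float        # pA, positive magnitude
    decay_tau: float | None
    is_failure: bool = False


@dataclass
class SEPSCStats:
    frequency: float             # Hz
    mean_amplitude: float        # pA
    decay_tau: float | None      # ms
    n_events: int
    sufficient: bool             # at least 50 events sampled


@dataclass
class UnitaryStats:
    potency: float | None        # pA
    amplitude: float             # pA
    failure_probability: float
    latency: float | None        # ms
    decay_tau: float | None      # ms
    n_events: int


@dataclass
class TrainResult:
    pulse_amplitude: np.ndarray  # normalized to pulse 1
    pulse_failure_rate: np.ndarray
    end_depression: float        # 1 - mean(pulses 21-25)/pulse 1
    end_failure_rate: float


def _fit_decay(t: np.ndarray, y: np.ndarray) -> float | None:
    """Single-exponential decay constant of a (positive) transient."""
    if len(t) < 5 or y.max() <= 0:
        return None
    try:
        popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau),
                            t, y, p0=(float(y[0]), 5.0), maxfev=2000,
                            bounds=([0, 0.05], [np.inf, 500]))
    except RuntimeError:
        return None
    return float(popt[1])


# ---------------------------------------------------------------------------
# spontaneous events
# ---------------------------------------------------------------------------

def detect_sepsc(trace: Trace, k_sd: float = 4.0,
                 refractory_ms: float = 2.0, smooth_ms: float = 0.3):
    """Detect spontaneous inward events by amplitude threshold.

    The lightly band-limited (boxcar-smoothed) trace is compared against
    ``k_sd`` times the robust (MAD) baseline SD of the raw trace; a
    hysteresis state machine (re-arm at half threshold) plus the
    refractory period yields one detection per excursion.  Returns
    (events, SEPSCStats).
    """
    if trace.duration_ms < 1000.0:
        raise InsufficientDataError("detect_sepsc needs >= 1 s of recording")
    dt = trace.time_step
    i = trace.current
    w = max(1, int(round(smooth_ms / dt)))
    sm = np.convolve(i, np.ones(w) / w, mode="same")
    med = float(np.median(sm))
    # k times the robust (MAD) SD of the *raw* trace — the baseline noise a
    # rig would quote — so pure noise rarely crosses even after smoothing
    sd_i = 1.4826 * np.median(np.abs(i - np.median(i)))
    amp_min = k_sd * max(sd_i, 1e-12)
    x = med - sm  # positive-going event signal
    # hysteresis state machine: trigger on crossing amp_min, re-arm only
    # after recovery below amp_min / 2 — one detection per excursion
    refr = int(round(refractory_ms / dt))
    half_win = int(round(5.0 / dt))
    hi_cross = np.flatnonzero((x[1:] >= amp_min) & (x[:-1] < amp_min)) + 1
    events = []
    rearm_at = 0
    for j in hi_cross:
        if j < rearm_at:
            continue
        # event span: until recovery below half-threshold
        rec = np.flatnonzero(x[j:] < amp_min / 2.0)
        end = j + (int(rec[0]) if len(rec) else len(x) - j)
        pk = j + int(np.argmax(x[j:max(end, j + 1)]))
        base = float(np.median(sm[max(0, j - half_win):j])) if j else med
        amp = base - sm[pk]
        rearm_at = max(end, j + refr)
        if amp < amp_min:
            continue
        events.append(DetectedEvent(onset_time=j * dt,
                                    peak_amplitude=float(amp),
                                    decay_tau=None))
    freq = len(events) / (trace.duration_ms / 1000.0)
    amp = float(np.mean([e.peak_amplitude for e in events])) if events else 0.0
    # average-aligned event for the decay fit
    tau = None
    if len(events) >= 5:
        span = int(round(20.0 / dt))
        snips = []
        for e in events:
            j = int(round(e.onset_time / dt))
            if j + span < len(sm):
                base = float(np.median(sm[max(0, j - half_win):j])) if j else 0.0
                snips.append(base - sm[j:j + span])
        if snips:
            avg = np.mean(snips, axis=0)
            pk = int(np.argmax(avg))
            t = np.arange(len(avg) - pk) * dt
            tau = _fit_decay(t, avg[pk:])
    stats = SEPSCStats(frequency=freq, mean_amplitude=amp, decay_tau=tau,
                       n_events=len(events), sufficient=len(events) >= 50)
    return events, stats


# ---------------------------------------------------------------------------
# unitary transmission
# ---------------------------------------------------------------------------

def _trial_responses(pair: PairedRecording, fail_k: float = FAIL_K_SD):
    """Per-(trial, AP) peak magnitudes, failure calls and baselines.

    Returns (amps, fails, base_sd, peak_idx) arrays of shape
    (n_trials, n_aps).
    """
    dt = pair.dt_ms
    w0 = int(round(RESPONSE_WINDOW_MS[0] / dt))
    w1 = int(round(RESPONSE_WINDOW_MS[1] / dt))
    nb = int(round(BASELINE_MS / dt))
    # the baseline *mean* uses only the last 0.5 ms before the AP so that,
    # in 50 Hz trains, the decaying tail of the previous IPSC cancels
    # rather than biasing the next response; the SD keeps the longer window
    nb_mean = max(1, int(round(0.5 / dt)))
    n_tr, n = pair.trials.shape
    n_ap = len(pair.ap_times_ms)
    amps = np.zeros((n_tr, n_ap))
    fails = np.zeros((n_tr, n_ap), dtype=bool)
    for k, t_ap in enumerate(pair.ap_times_ms):
        j = int(round(t_ap / dt))
        b0 = max(0, j - nb)
        for tr in range(n_tr):
            base_seg = pair.trials[tr, b0:j] if j > b0 else pair.trials[tr, :1]
            base = float(np.mean(base_seg[-nb_mean:]))
            # SD floor keeps the failure criterion meaningful on noise-free
            # synthetic trials
            sd = max(float(np.std(base_seg)) if len(base_seg) > 1 else 0.0,
                     1e-3)
            seg = pair.trials[tr, j + w0:j + w1]
            if not len(seg):
                fails[tr, k] = True
                continue
            amp = base - seg.min()      # inward: negative deflection
            amps[tr, k] = max(amp, 0.0)
            fails[tr, k] = amp < fail_k * sd
    return amps, fails


def unitary_stats(pair: PairedRecording, fail_k: float = FAIL_K_SD) -> UnitaryStats:
    """Basal unitary properties from repeated single-AP trials.

    Every AP across every trial counts as one event (basal protocols use
    one AP per trial).  Requires at least 10 events.
    """
    n_events = pair.n_trials * len(pair.ap_times_ms)
    if n_events < 10:
        raise InsufficientDataError(
            f"unitary_stats needs >= 10 AP trials, got {n_events}")
    amps, fails = _trial_responses(pair, fail_k)
    flat_amp = amps.ravel()
    flat_fail = fails.ravel()
    pf = float(flat_fail.mean())
    succ = flat_amp[~flat_fail]
    if len(succ) == 0:
        return UnitaryStats(potency=None, amplitude=0.0,
                            failure_probability=1.0, latency=None,
                            decay_tau=None, n_events=n_events)
    potency = float(succ.mean())
    amplitude = float(np.where(flat_fail, 0.0, flat_amp).mean())

    dt = pair.dt_ms
    lat_thresh = 0.05 * potency
    latencies = []
    snips = []
    span = int(round(40.0 / dt))
    nb = int(round(BASELINE_MS / dt))
    for k, t_ap in enumerate(pair.ap_times_ms):
        j = int(round(t_ap / dt))
        for tr in range(pair.n_trials):
            if fails[tr, k]:
                continue
            base = float(np.mean(pair.trials[tr, max(0, j - nb):j])) if j else 0.0
            seg = base - pair.trials[tr, j:j + span]  # positive transient
            cross = np.flatnonzero(seg >= lat_thresh)
            if len(cross):
                latencies.append(cross[0] * dt)
            snips.append(seg)
    latency = float(np.mean(latencies)) if latencies else None
    tau = None
    if snips:
        avg = np.mean([s for s in snips if len(s) == span], axis=0)
        pk = int(np.argmax(avg))
        t = np.arange(len(avg) - pk) * dt
        tau = _fit_decay(t, avg[pk:])
    return UnitaryStats(potency=potency, amplitude=amplitude,
                        failure_probability=pf, latency=latency,
                        decay_tau=tau, n_events=n_events)


def train_dynamics(pair: PairedRecording, n_pulses: int = 25,
                   fail_k: float = FAIL_K_SD) -> TrainResult:
    """Short-term dynamics over repeated high-frequency trains."""
    if len(pair.ap_times_ms) != n_pulses:
        raise ValueError(
            f"expected {n_pulses} pulses, got {len(pair.ap_times_ms)}")
    if pair.n_trials < 5:
        raise InsufficientDataError(
            f"train_dynamics needs >= 5 trials, got {pair.n_trials}")
    amps, fails = _trial_responses(pair, fail_k)
    eff = np.where(fails, 0.0, amps)
    mean_amp = eff.mean(axis=0)
    if mean_amp[0] <= 0:
        raise InsufficientDataError("pulse 1 failed on every trial")
    norm = mean_amp / mean_amp[0]
    fail_rate = fails.mean(axis=0)
    end = slice(20, 25)
    return TrainResult(
        pulse_amplitude=norm,
        pulse_failure_rate=fail_rate,
        end_depression=float(1.0 - mean_amp[end].mean() / mean_amp[0]),
        end_failure_rate=float(fails[:, end].mean()),
    )


def connection_probability(tested: int, connected: int, conf: float = 0.95):
    """Connection fraction with a Clopper-Pearson interval.

    Returns (fraction, (lo, hi)).
    """
    if tested <= 0:
        raise ValueError("tested must be > 0")
    if not (0 <= connected <= tested):
        raise ValueError("need 0 <= connected <= tested")
    a = (1 - conf) / 2
    lo = 0.0 if connected == 0 else float(beta.ppf(a, connected,
                                                   tested - connected + 1))
    hi = 1.0 if connected == tested else float(beta.ppf(1 - a, connected + 1,
                                                        tested - connected))
    return connected / tested, (lo, hi)
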