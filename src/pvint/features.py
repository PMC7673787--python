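"""Intrinsic membrane and firing feature extraction from current-clamp sweeps.

Operational definitions
-----------------------
* AP threshold: the voltage at which the rising-phase slope trajectory
  first reaches 10 mV/ms (centred-difference derivative).
* AP amplitude: threshold to peak.  Half-width: width at threshold +
  amplitude/2, with linear interpolation of the crossings.
* AHP amplitude: threshold voltage minus the most negative potential
  between the peak and the next spike's threshold (or +50 ms).
* Input resistance: least-squares slope of steady-state deflection (mean
  of the last 200 ms of the step, minus baseline) against step current.
* Membrane time constant: single-exponential fit to the averaged response
  onset of repeated -20 pA pulses (fit window onset +0.5 to +80 ms, short
  relative to the slow sag so the single-exponential stays unbiased).
* Firing frequency: spike count in the first 500 ms of the train / 0.5 s;
  adaptation ratio: mean of the last three ISIs over the first three
  (defined only with >= 7 spikes).  When the 3x-rheobase sweep is in
  depolarization block, FF3x falls back to the maximum firing frequency
  across non-blocked sweeps.
* Sag index: (Vrest - Vsag) / (Vrest - Vhyp) on the hyperpolarizing sweep
  whose steady-state voltage lies closest to -80 mV.
* Depolarization block: a sweep is blocked when spiking ceases before 80%
  of the step while the mean voltage over the final third of the step
  stays above the cell's AP threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import CellRecording, InsufficientDataError, Trace

#: dV/dt criterion for the AP threshold, mV/ms
SLOPE_THRESHOLD = 10.0
#: spike peaks must exceed this voltage, mV
PEAK_MIN_MV = -10.0
#: minimum peak separation, ms
REFRACTORY_MS = 1.0
#: steady-state averaging window at the end of a step, ms
STEADY_MS = 200.0
#: block criterion: spiking must cease before this fraction of the step...
BLOCK_CEASE_FRAC = 0.8
#: ...while the mean V over this final fraction exceeds the AP threshold
BLOCK_PLATEAU_FRAC = 1.0 / 3.0


@dataclass
class SpikeEvent:
    threshold_time: float
    threshold_V: float
    peak_time: float
    peak_V: float
    half_width: float
    ahp_V: float
    max_rise: float
    max_decay: float

    @property
    def amplitude(self) -> float:
        return self.peak_V - self.threshold_V


@dataclass
class IntrinsicFeatures:
    """The per-cell feature record.  Unmeasurable fields are None and the
    reason is recorded in ``nulls``."""

    cell_id: str = ""
    genotype: str = "WT"
    rin: float | None = None            # MOhm
    tau_m: float | None = None          # ms
    cm: float | None = None             # pF
    rheobase: float | None = None       # pA
    ap_threshold: float | None = None   # mV
    ap_amplitude: float | None = None   # mV
    ap_halfwidth: float | None = None   # ms
    ahp_amplitude: float | None = None  # mV (negative)
    max_rise: float | None = None       # mV/ms
    max_decay: float | None = None      # mV/ms (negative)
    ff_2x: float | None = None          # Hz
    ff_3x: float | None = None          # Hz
    ar_2x: float | None = None
    ar_3x: float | None = None
    sag_index: float | None = None
    block_current: float | None = None  # pA; None when censored at 1500
    entered_block: bool = False
    nulls: dict = field(default_factory=dict)

    #: the seven features used for subtype clustering
    CLUSTER_FEATURES = ("ap_halfwidth", "ff_2x", "ff_3x", "ar_2x",
                        "rin", "rheobase", "sag_index")

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            if f.name == "nulls":
                continue
            out[f.name] = getattr(self, f.name)
        return out


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, window: tuple | None = None) -> list:
    """Detect action potentials and their waveform metrics.

    ``window`` restricts detection to (t0_ms, t1_ms).  Returns an empty
    list when the trace contains no spikes.
    """
    v = trace.voltage
    dt = trace.time_step
    n = len(v)
    i0, i1 = 0, n
    if window is not None:
        i0 = max(0, int(round(window[0] / dt)))
        i1 = min(n, int(round(window[1] / dt)))
    if i1 - i0 < 3:
        return []
    dvdt = np.empty(n)
    dvdt[1:-1] = (v[2:] - v[:-2]) / (2 * dt)
    dvdt[0] = dvdt[1]
    dvdt[-1] = dvdt[-2]

    peaks, _ = find_peaks(v[i0:i1], height=PEAK_MIN_MV,
                          distance=max(1, int(round(REFRACTORY_MS / dt))))
    peaks = peaks + i0
    look_back = int(round(10.0 / dt))
    events = []
    for pi, peak in enumerate(peaks):
        lo = max(i0, peak - look_back)
        j = peak - 1
        while j > lo and dvdt[j] < SLOPE_THRESHOLD:
            j -= 1
        if dvdt[j] < SLOPE_THRESHOLD:
            continue  # no 10 mV/ms rising phase: not a spike
        while j - 1 > lo and dvdt[j - 1] >= SLOPE_THRESHOLD:
            j -= 1
        thr_i, thr_v = j, v[j]
        amp = v[peak] - thr_v
        if amp <= 0:
            continue
        v_half = thr_v + amp / 2.0

        def _interp_cross(a, b, rising):
            """Linear-interpolated time where v crosses v_half in [a, b)."""
            seg = v[a:b]
            if rising:
                idx = np.argmax(seg >= v_half)
            else:
                idx = np.argmax(seg <= v_half)
            k = a + idx
            if k == 0 or (rising and seg[idx] < v_half) or \
               (not rising and seg[idx] > v_half):
                return None
            v1, v2 = v[k - 1], v[k]
            if v2 == v1:
                return k * dt
            frac = (v_half - v1) / (v2 - v1)
            return (k - 1 + frac) * dt

        t_up = _interp_cross(thr_i, peak + 1, rising=True)
        # AHP window: to the next spike's vicinity or +50 ms
        ahp_end = min(n, peak + int(round(50.0 / dt)))
        if pi + 1 < len(peaks):
            ahp_end = min(ahp_end, peaks[pi + 1])
        t_dn = _interp_cross(peak, ahp_end, rising=False)
        if t_up is None or t_dn is None:
            half = np.nan
        else:
            half = t_dn - t_up
        trough_i = peak + int(np.argmin(v[peak:ahp_end])) if ahp_end > peak else peak
        events.append(SpikeEvent(
            threshold_time=thr_i * dt,
            threshold_V=thr_v,
            peak_time=peak * dt,
            peak_V=v[peak],
            half_width=half,
            ahp_V=v[trough_i],
            max_rise=float(dvdt[thr_i:peak + 1].max()),
            max_decay=float(dvdt[peak:trough_i + 1].min()) if trough_i > peak else np.nan,
        ))
    return events


# ---------------------------------------------------------------------------
# helpers on step sweeps
# ---------------------------------------------------------------------------

def _step_bounds(tr: Trace):
    dt = tr.time_step
    base = tr.meta.get("baseline_ms")
    step = tr.meta.get("step_ms")
    if base is None or step is None:
        raise InsufficientDataError(
            f"sweep {tr.sweep_id!r} lacks baseline_ms/step_ms metadata")
    a = int(round(base / dt))
    b = int(round((base + step) / dt))
    return a, min(b, len(tr.voltage))


def _steady_state(tr: Trace) -> float:
    a, b = _step_bounds(tr)
    k = int(round(STEADY_MS / tr.time_step))
    return float(tr.voltage[max(a, b - k):b].mean())


def _baseline(tr: Trace) -> float:
    a, _ = _step_bounds(tr)
    return float(tr.voltage[:a].mean()) if a > 0 else float(tr.voltage[0])


def _step_spikes(tr: Trace) -> list:
    a, b = _step_bounds(tr)
    return detect_spikes(tr, window=(a * tr.time_step, b * tr.time_step))


def _smooth(v: np.ndarray, dt: float, width_ms: float = 2.0) -> np.ndarray:
    w = max(1, int(round(width_ms / dt)))
    if w == 1:
        return v
    kern = np.ones(w) / w
    return np.convolve(v, kern, mode="same")


# ---------------------------------------------------------------------------
# passive features
# ---------------------------------------------------------------------------

def input_resistance(sweeps: list) -> float:
    """Input resistance (MOhm) from the steady-state V-I regression.

    Sweeps containing spikes are excluded.  Raises
    :class:`InsufficientDataError` with fewer than two usable amplitudes.
    """
    pts = []
    for tr in sweeps:
        if tr.step_pA is None:
            continue
        if _step_spikes(tr):
            continue
        pts.append((tr.step_pA, _steady_state(tr) - _baseline(tr)))
    if len({i for i, _ in pts}) < 2:
        raise InsufficientDataError(
            f"input_resistance needs >= 2 spike-free sweeps, got {len(pts)}")
    if len(pts) < 4:
        warnings.warn("input_resistance: fewer than 4 usable sweeps")
    i = np.array([p[0] for p in pts])
    dv = np.array([p[1] for p in pts])
    slope = np.polyfit(i, dv, 1)[0]  # mV / pA
    return float(slope * 1000.0)     # -> MOhm


def membrane_time_constant(sweeps: list, fit_ms: float = 80.0) -> float:
    """Membrane time constant (ms) from averaged hyperpolarizing pulses.

    Averages the aligned pulse responses and fits V(t) = V_inf + A
    exp(-t/tau) over (onset + 0.5 ms, onset + ``fit_ms``).  The default
    80 ms window spans several membrane time constants while staying short
    relative to the slow (>= 100 ms) H-current sag, which keeps the fit
    bias below 10% for tau_m up to 15 ms.
    """
    if len(sweeps) < 5:
        raise InsufficientDataError(
            f"membrane_time_constant needs >= 5 pulse repetitions, got {len(sweeps)}")
    dt = sweeps[0].time_step
    a, b = _step_bounds(sweeps[0])
    nmin = min(len(tr.voltage) for tr in sweeps)
    avg = np.mean([tr.voltage[:nmin] for tr in sweeps], axis=0)
    j0 = a + max(1, int(round(0.5 / dt)))
    j1 = min(b, a + int(round(fit_ms / dt)), nmin)
    t = (np.arange(j0, j1) - a) * dt
    y = avg[j0:j1]

    def model(tt, v_inf, amp, tau):
        return v_inf + amp * np.exp(-tt / tau)

    p0 = (float(y[-1]), float(y[0] - y[-1]), 10.0)
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=5000,
                            bounds=([-150, -100, 0.1], [50, 100, 500]))
    except RuntimeError as e:
        rss = float(np.sum((y - model(t, *p0)) ** 2))
        raise RuntimeError(
            f"membrane_time_constant fit failed (RSS at init {rss:.3g}): {e}")
    return float(popt[2])


def capacitance(rin: float, tau_m: float) -> float:
    """Membrane capacitance in pF: Cm = 1000 * tau_m / Rin."""
    if rin <= 0 or tau_m <= 0:
        raise ValueError("rin and tau_m must be > 0")
    return 1000.0 * tau_m / rin


# ---------------------------------------------------------------------------
# firing features
# ---------------------------------------------------------------------------

def rheobase(sweeps: list) -> float | None:
    """Smallest step amplitude evoking at least one spike; None if censored."""
    for tr in sorted(sweeps, key=lambda s: s.step_pA or 0.0):
        if tr.step_pA is None or tr.step_pA <= 0:
            continue
        if _step_spikes(tr):
            return float(tr.step_pA)
    return None


def _sweep_is_blocked(tr: Trace, ap_threshold: float) -> bool:
    a, b = _step_bounds(tr)
    dt = tr.time_step
    step_ms = (b - a) * dt
    spikes = _step_spikes(tr)
    last = max((s.threshold_time for s in spikes), default=a * dt)
    ceased = (last - a * dt) < BLOCK_CEASE_FRAC * step_ms
    j = b - int(round(BLOCK_PLATEAU_FRAC * (b - a)))
    plateau = float(tr.voltage[j:b].mean()) > ap_threshold
    return ceased and plateau


def _train_stats(tr: Trace):
    """(FF Hz, AR or None) over the first 500 ms of the step."""
    a, _ = _step_bounds(tr)
    dt = tr.time_step
    t0 = a * dt
    spikes = [s for s in _step_spikes(tr) if s.threshold_time < t0 + 500.0]
    ff = len(spikes) / 0.5
    ar = None
    if len(spikes) >= 7:
        isis = np.diff([s.threshold_time for s in spikes])
        ar = float(np.mean(isis[-3:]) / np.mean(isis[:3]))
    return ff, ar


def firing_frequency(sweeps: list, rheo: float, k: int,
                     ap_threshold: float | None = None):
    """(FF Hz, adaptation ratio) at the sweep nearest k-times rheobase.

    With ``ap_threshold`` given and the target sweep in depolarization
    block, FF falls back to the maximum across non-blocked sweeps (the
    standard substitution for 3x trains) and AR comes from that sweep.
    """
    usable = [tr for tr in sweeps if tr.step_pA and tr.step_pA > 0]
    if not usable:
        raise InsufficientDataError("no positive-current sweeps")
    target = k * rheo
    tr = min(usable, key=lambda s: (abs(s.step_pA - target), s.step_pA))
    if ap_threshold is not None and _sweep_is_blocked(tr, ap_threshold):
        unblocked = [s for s in usable if not _sweep_is_blocked(s, ap_threshold)]
        if not unblocked:
            return None, None
        stats = [(_train_stats(s), s) for s in unblocked]
        (ff, ar), _ = max(stats, key=lambda x: x[0][0])
        return ff, ar
    return _train_stats(tr)


def sag_index(sweeps: list, vrest: float | None = None) -> float:
    """Sag index on the hyperpolarizing sweep with steady state nearest -80 mV."""
    hyp = [tr for tr in sweeps if tr.step_pA is not None and tr.step_pA < 0]
    if not hyp:
        raise InsufficientDataError("sag_index needs a hyperpolarizing sweep")
    tr = min(hyp, key=lambda s: abs(_steady_state(s) + 80.0))
    a, b = _step_bounds(tr)
    vr = _baseline(tr) if vrest is None else vrest
    vsag = _steady_state(tr)
    vhyp = float(_smooth(tr.voltage, tr.time_step)[a:b].min())
    denom = vr - vhyp
    if abs(denom) < 1e-9:
        return 1.0
    return float((vr - vsag) / denom)


def block_current(sweeps: list, ap_threshold: float):
    """(first blocked step amplitude or None-censored, entered_block)."""
    for tr in sorted(sweeps, key=lambda s: s.step_pA or 0.0):
        if tr.step_pA is None or tr.step_pA <= 0:
            continue
        if _sweep_is_blocked(tr, ap_threshold):
            return float(tr.step_pA), True
    return None, False


def classify_block_in_continuous(sweeps: list, ap_threshold: float,
                                 skip_first_s: float = 60.0) -> bool:
    """True when any evoked window after the skip period shows block."""
    windows_seen = 0
    elapsed_s = 0.0
    for tr in sweeps:
        wins = tr.meta.get("evoked_windows") or []
        for start_ms, dur_ms in wins:
            windows_seen += 1
            if elapsed_s < skip_first_s:
                continue
            sub = Trace(time_step=tr.time_step, voltage=tr.voltage,
                        current=tr.current, sweep_id=tr.sweep_id,
                        protocol_tag=tr.protocol_tag,
                        meta={"baseline_ms": start_ms, "step_ms": dur_ms})
            if _sweep_is_blocked(sub, ap_threshold):
                return True
        elapsed_s += tr.duration_ms / 1000.0
    if windows_seen == 0:
        raise InsufficientDataError("no evoked windows marked")
    return False


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def extract_all(rec: CellRecording) -> IntrinsicFeatures:
    """Populate the full feature record; unmeasurable fields become None
    with a reason code in ``nulls`` instead of aborting the record."""
    out = IntrinsicFeatures(cell_id=rec.cell_id, genotype=rec.genotype)
    sub = rec.by_protocol("subthreshold_steps")
    tau = rec.by_protocol("tau_pulses")
    fir = rec.by_protocol("firing_steps")
    ramp = rec.by_protocol("block_ramp")

    def attempt(name, fn):
        try:
            return fn()
        except Exception as e:  # per-feature nulls, never abort the record
            out.nulls[name] = f"{type(e).__name__}: {e}"
            return None

    out.rin = attempt("rin", lambda: input_resistance(sub))
    out.tau_m = attempt("tau_m", lambda: membrane_time_constant(tau))
    if out.rin and out.tau_m:
        out.cm = capacitance(out.rin, out.tau_m)
    else:
        out.nulls.setdefault("cm", "requires rin and tau_m")
    out.sag_index = attempt("sag_index", lambda: sag_index(sub))

    if not fir:
        out.nulls["rheobase"] = "no firing_steps sweeps"
        return out
    out.rheobase = attempt("rheobase", lambda: rheobase(fir))
    if out.rheobase is None:
        out.nulls.setdefault("rheobase", "no sweep elicited spikes")
        return out

    rheo_sweep = min((t for t in fir if t.step_pA and t.step_pA > 0),
                     key=lambda s: abs(s.step_pA - out.rheobase))
    spikes = _step_spikes(rheo_sweep)
    if spikes:
        s0 = spikes[0]
        out.ap_threshold = s0.threshold_V
        out.ap_amplitude = s0.amplitude
        out.ap_halfwidth = None if np.isnan(s0.half_width) else s0.half_width
        out.ahp_amplitude = s0.ahp_V - s0.threshold_V
        out.max_rise = s0.max_rise
        out.max_decay = None if np.isnan(s0.max_decay) else s0.max_decay

    thr = out.ap_threshold
    ff2 = attempt("ff_2x", lambda: firing_frequency(fir, out.rheobase, 2, thr))
    if ff2 is not None:
        out.ff_2x, out.ar_2x = ff2
        if out.ar_2x is None:
            out.nulls["ar_2x"] = "fewer than 7 spikes at 2x rheobase"
    ff3 = attempt("ff_3x", lambda: firing_frequency(fir, out.rheobase, 3, thr))
    if ff3 is not None:
        out.ff_3x, out.ar_3x = ff3
        if out.ar_3x is None:
            out.nulls["ar_3x"] = "fewer than 7 spikes at 3x rheobase"

    if ramp and thr is not None:
        out.block_current, out.entered_block = block_current(ramp, thr)
    else:
        out.nulls["block_current"] = "no block_ramp sweeps or no AP threshold"
    return out


def features_dataframe(records: list):
    """DataFrame of feature records (one row per cell)."""
    import pandas as pd

    return pd.DataFrame([f.to_dict() for f in records]).set_index("cell_id")
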