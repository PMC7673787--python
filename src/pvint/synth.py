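"""Synthetic cells, synaptic pairs and morphologies with controlled statistics.

The generator exists so that every pipeline stage can be exercised, and its
estimators validated, without any recorded data.  It is a hybrid
phenomenological model rather than a conductance model:

* Subthreshold responses are a leaky-RC charge curve plus a slow
  H-current-like relaxation that produces the hyperpolarization sag; the
  peak deflection is calibrated numerically so the *measured* sag index
  equals the designed one.
* Suprathreshold sweeps are built by scheduling spike times from a designed
  per-cell f-I curve (piecewise linear through rheobase, 2x and 3x
  rheobase) with a geometric inter-spike-interval progression that realizes
  the designed adaptation ratio exactly, then splicing a parametric action
  potential waveform whose threshold, amplitude, half-width, AHP depth and
  maximal rise/decay slopes are the designed values.
* Above a per-cell block current the cell fires briefly and then sits on a
  suprathreshold plateau (depolarization block).

Direct control of every intrinsic feature is the point: parameter-recovery
tests are well-posed because the ground truth is the drawn feature itself.
Rheobase and block current are realized on the 50 pA stimulus grid at draw
time, since a finer value is unobservable under the step protocol.

Per-subtype parameter presets (``SUBTYPE_TABLE``) carry the published
per-genotype feature means with dispersion SD = SEM * sqrt(n), applied on
the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CellRecording,
    DEFAULT_DT_MS,
    PairedRecording,
    StepProtocol,
    Trace,
)
from .morphology import NeuriteTree, SWCNode

STEP_GRID_PA = 50.0
MAX_STEP_PA = 1500.0
#: slow sag relaxation time constant, ms
TAU_H_MS = 150.0
#: default recording noise, mV (voltage) and pA (current)
NOISE_V_SD = 0.2
NOISE_I_SD = 3.0


# ---------------------------------------------------------------------------
# per-subtype parameter presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeParams:
    """Feature means/SEMs for one physiological subtype in one genotype.

    ``means``/``sems`` are keyed by feature name.  ``n_ref`` is the sample
    size behind the SEMs (dispersion SD = SEM * sqrt(n_ref)).  ``block``
    holds (fraction_blocking, mean_pA, sem_pA) of the depolarization-block
    current; cells drawn as non-blocking never block below 1500 pA.
    """

    label: str
    genotype: str
    means: dict
    sems: dict
    n_ref: int
    n_cells: int
    block: tuple  # (fraction_blocking, mean_pA, sem_pA)

    def with_n_cells(self, n: int) -> "SubtypeParams":
        return replace(self, n_cells=n)


_F = ("rin", "rheobase", "ff2x", "ar2x", "ff3x", "ar3x", "ap_threshold",
      "ap_halfwidth", "ap_amplitude", "max_rise", "max_decay", "ahp",
      "tau_m", "sag")


def _params(label, genotype, n, vals, sems, block):
    return SubtypeParams(
        label=label, genotype=genotype,
        means=dict(zip(_F, vals)), sems=dict(zip(_F, sems)),
        n_ref=n, n_cells=n, block=block,
    )


#: Published per-genotype, per-subtype feature means and SEMs.  Order of
#: values follows ``_F``.  Block tuples: FS cells are mostly resistant
#: (about a quarter block, near 1.2-1.3 nA); IS cells block at 990 +/- 80;
#: NFS cells always block near 690-700 pA.
SUBTYPE_TABLE = {
    ("WT", "FS"): _params(
        "FS", "WT", 67,
        (82.5, 364.2, 137.6, 0.79, 170.9, 0.78, -39.9, 0.42, 61.1,
         259.9, -188.7, -16.8, 8.5, 0.90),
        (3.6, 17.3, 4.7, 0.02, 5.1, 0.01, 0.7, 0.01, 1.0,
         5.2, 5.5, 0.6, 0.5, 0.01),
        (0.23, 1230.0, 180.0)),
    ("GlobalLis", "FS"): _params(
        "FS", "GlobalLis", 20,
        (63.5, 457.5, 168.5, 0.80, 216.5, 0.82, -41.2, 0.34, 61.2,
         248.3, -176.0, -17.5, 7.5, 0.91),
        (4.2, 22.2, 11.2, 0.03, 11.5, 0.03, 1.2, 0.01, 2.7,
         13.5, 14.3, 0.9, 0.4, 0.01),
        (0.30, 1280.0, 110.0)),
    ("NkxLis", "FS"): _params(
        "FS", "NkxLis", 12,
        (61.1, 533.3, 173.2, 0.72, 213.0, 0.71, -39.9, 0.35, 55.8,
         268.6, -201.6, -15.3, 6.7, 0.95),
        (6.3, 42.3, 14.8, 0.04, 15.3, 0.05, 1.3, 0.01, 3.0,
         11.7, 9.1, 0.9, 0.4, 0.01),
        (0.25, 1250.0, 150.0)),
    ("EmxLis", "FS"): _params(
        "FS", "EmxLis", 30,
        (75.0, 463.3, 155.4, 0.71, 195.7, 0.71, -37.8, 0.36, 57.5,
         217.0, -211.4, -16.7, 8.6, 0.92),
        (4.7, 24.8, 7.4, 0.02, 10.3, 0.02, 1.1, 0.01, 2.0,
         12.1, 12.6, 0.7, 0.4, 0.01),
        (0.25, 1250.0, 150.0)),
    ("GlobalLis", "IS"): _params(
        "IS", "GlobalLis", 21,
        (88.5, 340.5, 106.2, 0.71, 130.2, 0.67, -40.4, 0.48, 62.1,
         261.4, -198.1, -16.3, 8.7, 0.90),
        (4.9, 20.0, 4.8, 0.03, 6.0, 0.02, 1.1, 0.01, 2.3,
         10.7, 12.6, 0.8, 0.4, 0.01),
        (0.92, 990.0, 80.0)),
    ("NkxLis", "IS"): _params(
        "IS", "NkxLis", 21,
        (85.5, 342.9, 95.6, 0.65, 131.1, 0.57, -35.9, 0.44, 53.6,
         231.0, -149.2, -16.0, 8.5, 0.91),
        (7.0, 21.1, 3.5, 0.03, 5.1, 0.03, 1.2, 0.01, 2.0,
         10.3, 7.1, 1.0, 0.7, 0.01),
        (0.92, 990.0, 80.0)),
    ("WT", "NFS"): _params(
        "NFS", "WT", 16,
        (143.1, 153.1, 66.0, 0.67, 96.1, 0.65, -40.6, 0.59, 65.4,
         228.6, -136.5, -15.7, 10.9, 0.80),
        (11.9, 14.8, 4.5, 0.03, 4.6, 0.03, 1.2, 0.02, 3.2,
         11.5, 11.5, 1.2, 0.6, 0.03),
        (1.0, 690.0, 110.0)),
    ("GlobalLis", "NFS"): _params(
        "NFS", "GlobalLis", 4,
        (132.0, 162.5, 57.0, 0.79, 74.5, 0.64, -38.6, 0.64, 64.8,
         210.3, -131.3, -16.9, 12.9, 0.82),
        (14.4, 20.0, 11.6, 0.05, 15.1, 0.10, 2.8, 0.07, 7.0,
         25.0, 20.6, 1.1, 0.6, 0.04),
        (1.0, 700.0, 200.0)),
    ("NkxLis", "NFS"): _params(
        "NFS", "NkxLis", 8,
        (200.7, 125.0, 72.3, 0.79, 100.8, 0.73, -36.8, 0.56, 55.1,
         197.9, -119.2, -17.0, 14.8, 0.86),
        (17.0, 13.4, 4.4, 0.06, 5.7, 0.05, 1.2, 0.04, 5.7,
         18.3, 14.7, 1.2, 1.6, 0.02),
        (1.0, 690.0, 110.0)),
    ("EmxLis", "NFS"): _params(
        "NFS", "EmxLis", 8,
        (173.2, 143.8, 58.0, 0.52, 77.8, 0.47, -36.8, 0.58, 64.9,
         241.0, -125.4, -11.3, 17.1, 1.0,),
        (9.0, 11.3, 3.5, 0.05, 6.9, 0.05, 1.3, 0.04, 4.8,
         26.0, 16.8, 1.7, 1.0, 0.02),
        (1.0, 690.0, 110.0)),
}
# EmxLis NFS sag: reported 0.85 +/- 0.02
SUBTYPE_TABLE[("EmxLis", "NFS")].means["sag"] = 0.85

#: Cohort compositions (cells per subtype) per genotype.
COHORT_COMPOSITION = {
    "WT": {"FS": 67, "NFS": 16},
    "GlobalLis": {"FS": 20, "IS": 21, "NFS": 4},
    "NkxLis": {"FS": 12, "IS": 21, "NFS": 8},
    "EmxLis": {"FS": 30, "NFS": 8},
}


# ---------------------------------------------------------------------------
# per-cell realized specification
# ---------------------------------------------------------------------------

@dataclass
class SynthCellSpec:
    """Realized parameters of one synthetic cell.

    Units follow the package conventions (mV / pA / ms / MOhm).
    ``rheobase`` and ``block_current`` lie on the 50 pA stimulus grid;
    ``block_current`` is None for cells resistant below 1500 pA.
    ``max_decay`` and ``ahp`` are negative, matching the sign convention of
    the reported features.
    """

    cell_id: str = "cell"
    genotype: str = "WT"
    label: str = "FS"
    vrest: float = -65.0
    rin: float = 82.5
    tau_m: float = 8.5
    rheobase: float = 400.0
    ap_threshold: float = -39.9
    ap_amplitude: float = 61.1
    ap_halfwidth: float = 0.42
    ahp: float = -16.8
    max_rise: float = 259.9
    max_decay: float = -188.7
    ff2x: float = 137.6
    ff3x: float = 170.9
    ar2x: float = 0.79
    ar3x: float = 0.78
    sag: float = 0.90
    block_current: float | None = None
    noise_v: float = NOISE_V_SD
    seed: int = 0

    # implied passive parameters (leak conductance nS, capacitance pF)
    @property
    def g_leak_nS(self) -> float:
        return 1000.0 / self.rin

    @property
    def capacitance_pF(self) -> float:
        return 1000.0 * self.tau_m / self.rin

    def f_rate(self, step_pA: float) -> float:
        """Designed firing rate (Hz) at a given step current.

        Piecewise linear through (rheobase, 2 Hz), (2x, ff2x), (3x, ff3x);
        extrapolated with the final slope above 3x and capped at 400 Hz.
        Zero below rheobase and (if the cell blocks) at or above the block
        current.
        """
        r = self.rheobase
        if step_pA < r - 1e-9:
            return 0.0
        if self.block_current is not None and step_pA >= self.block_current - 1e-9:
            return 0.0
        pts_i = np.array([r, 2 * r, 3 * r])
        pts_f = np.array([2.0, self.ff2x, self.ff3x])
        if step_pA <= 3 * r:
            f = float(np.interp(step_pA, pts_i, pts_f))
        else:
            slope = (self.ff3x - self.ff2x) / r
            f = self.ff3x + slope * (step_pA - 3 * r)
        return min(f, 400.0)

    def adaptation(self, step_pA: float) -> float:
        r = self.rheobase
        pts = np.array([2 * r, 3 * r])
        vals = np.array([self.ar2x, self.ar3x])
        return float(np.interp(step_pA, pts, vals))


def _lognormal(rng, mean, sd, lo=None, hi=None, sign=1.0):
    """Draw with arithmetic mean ``mean`` and SD ``sd`` on a log-normal,
    applied to the magnitude (``sign`` restores negative-valued features)."""
    mean = abs(mean)
    cv = sd / mean if mean > 0 else 0.0
    s2 = math.log1p(cv * cv)
    x = rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2))
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return sign * x


def _grid(x: float, grid: float = STEP_GRID_PA) -> float:
    return float(math.ceil(x / grid - 1e-9) * grid)


def draw_cell_spec(params: SubtypeParams, rng: np.random.Generator,
                   cell_id: str = "cell", seed: int = 0,
                   noise_v: float = NOISE_V_SD) -> SynthCellSpec:
    """Realize one cell from subtype-level feature distributions.

    Dispersion is SEM * sqrt(n_ref) on the log scale.  Hard clips keep the
    realization inside the step protocol's observable range (rheobase at or
    above 100 pA on the 50 pA grid; the block current, when present, at
    least two grid steps above 2x rheobase so the 2x train is never cut
    short; sag in (0.5, 1]).
    """
    m, s, n = params.means, params.sems, params.n_ref
    sd = {k: s[k] * math.sqrt(n) for k in s}
    d = lambda k, **kw: _lognormal(rng, m[k], sd[k], **kw)

    rheo = _grid(d("rheobase", lo=90.0, hi=1400.0))
    ff2x = d("ff2x", lo=20.0)
    ff3x = max(d("ff3x", lo=25.0), ff2x + 5.0)
    frac_block, b_mean, b_sem = params.block
    if rng.uniform() < frac_block:
        b_sd = b_sem * math.sqrt(max(2, round(frac_block * n)))
        lo = 2 * rheo + 2 * STEP_GRID_PA
        block = _grid(min(max(_lognormal(rng, b_mean, b_sd), lo), MAX_STEP_PA))
    else:
        block = None
    thr = -d("ap_threshold", lo=25.0, hi=55.0)
    # spikes must overshoot the -10 mV peak criterion by a clear margin
    amp = max(d("ap_amplitude", lo=30.0), 5.0 - thr)
    return SynthCellSpec(
        cell_id=cell_id,
        genotype=params.genotype,
        label=params.label,
        vrest=-65.0 + rng.normal(0.0, 1.0),
        rin=d("rin", lo=20.0),
        tau_m=d("tau_m", lo=2.0),
        rheobase=rheo,
        ap_threshold=thr,
        ap_amplitude=amp,
        ap_halfwidth=d("ap_halfwidth", lo=0.15),
        ahp=-d("ahp", lo=4.0),
        max_rise=d("max_rise", lo=80.0),
        max_decay=-d("max_decay", lo=60.0),
        ff2x=ff2x,
        ff3x=ff3x,
        ar2x=d("ar2x", lo=0.2, hi=1.4),
        ar3x=d("ar3x", lo=0.2, hi=1.4),
        sag=d("sag", lo=0.5, hi=1.0),
        block_current=block,
        noise_v=noise_v,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# default protocols
# ---------------------------------------------------------------------------

def default_protocols(spec: SynthCellSpec) -> dict:
    """Standard protocol battery keyed by protocol tag.

    Six subthreshold steps (-200..+50 pA), twenty -20 pA / 400 ms pulses,
    firing steps from 50 pA in 50 pA increments through 3x rheobase, and a
    block ramp of 50 pA increments up to 1500 pA.
    """
    sub = [StepProtocol(100.0, 500.0, i, 100.0)
           for i in (-200.0, -150.0, -100.0, -50.0, 0.0, 50.0)]
    tau = [StepProtocol(100.0, 400.0, -20.0, 100.0) for _ in range(20)]
    top = min(3 * spec.rheobase, MAX_STEP_PA)
    firing = [StepProtocol(100.0, 500.0, i, 100.0)
              for i in np.arange(STEP_GRID_PA, top + 1e-6, STEP_GRID_PA)]
    ramp = [StepProtocol(100.0, 500.0, i, 100.0)
            for i in np.arange(STEP_GRID_PA, MAX_STEP_PA + 1e-6, STEP_GRID_PA)]
    return {"subthreshold_steps": sub, "tau_pulses": tau,
            "firing_steps": firing, "block_ramp": ramp}


# ---------------------------------------------------------------------------
# trace construction
# ---------------------------------------------------------------------------

def _subthreshold_trace(spec: SynthCellSpec, proto: StepProtocol,
                        dt: float, sag_active: bool = True) -> np.ndarray:
    """Closed-form passive response: RC charge plus slow sag relaxation.

    The fast-component amplitude is calibrated (secant iteration on the
    sampled trajectory) so the realized extremum of the deflection equals
    steady-state / sag exactly; the steady state itself is Rin * I, which
    keeps the input-resistance regression unbiased.
    """
    n = int(round(proto.total_ms / dt))
    v = np.full(n, spec.vrest)
    a = int(round(proto.baseline_ms / dt))
    b = int(round((proto.baseline_ms + proto.step_ms) / dt))
    t = (np.arange(a, b) - a) * dt
    dv_ss = spec.rin * proto.step_pA / 1000.0  # MOhm * pA -> mV
    if abs(dv_ss) < 1e-12:
        return v
    sag = spec.sag if sag_active else 1.0
    fast = lambda tt: 1.0 - np.exp(-tt / spec.tau_m)
    slow = lambda tt: 1.0 - np.exp(-tt / TAU_H_MS)
    target_ext = dv_ss / sag
    p = target_ext
    for _ in range(4):
        traj = p * fast(t) + (dv_ss - p) * slow(t)
        ext = traj[np.argmax(np.abs(traj))]
        if abs(ext) < 1e-12:
            break
        p *= target_ext / ext
    traj = p * fast(t) + (dv_ss - p) * slow(t)
    v[a:b] += traj
    if b < n:
        tail = (np.arange(b, n) - b) * dt
        v[b:] += traj[-1] * np.exp(-tail / spec.tau_m)
    return v


def _waveform_params(spec: SynthCellSpec):
    """Durations of the parametric AP template segments.

    The limbs are power laws |dV| ~ t**p; the exponent is set by the
    designed half-width relative to the slope-limited (triangular) minimum,
    clipped to [1.01, 6] so the waveform stays smooth at the peak.
    """
    amp, hw = spec.ap_amplitude, spec.ap_halfwidth
    mr, md = spec.max_rise, abs(spec.max_decay)
    p = 2.0 * hw / (amp * (1.0 / mr + 1.0 / md))
    p = float(np.clip(p, 1.01, 6.0))
    a = amp * p / (2.0 * mr)       # rise: below-half and above-half halves
    b = amp * p / (2.0 * md)       # fall: above-half
    d3 = amp / 2.0 + abs(spec.ahp)
    p3 = 1.5
    t3 = d3 * p3 / md              # fall: below-half, to the AHP trough
    return p, a, b, p3, t3


def _spike_template(spec: SynthCellSpec, dt: float):
    """Sampled AP waveform starting at the threshold point.

    Returns (samples, trough_index).  The trough sits at threshold + ahp.
    """
    p, a, b, p3, t3 = _waveform_params(spec)
    amp = spec.ap_amplitude
    thr = spec.ap_threshold
    vpeak = thr + amp
    vahp = thr + spec.ahp
    dur = 2 * a + b + t3
    t = np.arange(0.0, dur + dt, dt)
    v = np.empty_like(t)
    seg1 = t < a
    v[seg1] = thr + (amp / 2) * (t[seg1] / a) ** p
    seg2 = (t >= a) & (t < 2 * a)
    v[seg2] = vpeak - (amp / 2) * ((2 * a - t[seg2]) / a) ** p
    seg3 = (t >= 2 * a) & (t < 2 * a + b)
    v[seg3] = vpeak - (amp / 2) * ((t[seg3] - 2 * a) / b) ** p
    seg4 = t >= 2 * a + b
    w = np.minimum(t[seg4] - 2 * a - b, t3)
    d3 = amp / 2 + abs(spec.ahp)
    v[seg4] = vahp + d3 * ((t3 - w) / t3) ** p3
    trough = len(t) - 1
    return v, trough


def _isi_schedule(n_spikes: int, ar: float, window_ms: float, t0: float = 3.0):
    """Spike offsets (ms from window start) realizing the adaptation ratio.

    ISIs form a geometric progression: with m = n-1 intervals the ratio of
    the last-3 to first-3 interval means is exactly r**(m-3), so
    r = ar**(1/(m-3)).  The train is scaled to fill the window.
    """
    if n_spikes <= 0:
        return np.zeros(0)
    if n_spikes == 1:
        return np.array([t0])
    m = n_spikes - 1
    r = float(ar) ** (1.0 / (m - 3)) if m > 3 and ar > 0 else 1.0
    isis = r ** np.arange(m)
    avail = window_ms - t0 - 1.0
    isis *= avail / isis.sum()
    return t0 + np.concatenate([[0.0], np.cumsum(isis)])


def _splice(v: np.ndarray, idx: int, template: np.ndarray) -> int:
    """Overwrite v[idx:] with the template; return index just past it."""
    end = min(idx + len(template), len(v))
    v[idx:end] = template[: end - idx]
    return end


def _firing_trace(spec: SynthCellSpec, proto: StepProtocol, dt: float) -> np.ndarray:
    """A suprathreshold (or blocked) step response."""
    n = int(round(proto.total_ms / dt))
    a = int(round(proto.baseline_ms / dt))
    b = int(round((proto.baseline_ms + proto.step_ms) / dt))
    i_step = proto.step_pA
    blocked = (spec.block_current is not None
               and i_step >= spec.block_current - 1e-9)
    thr = spec.ap_threshold
    f = spec.f_rate(i_step)
    if not blocked and f <= 0:
        v = _subthreshold_trace(spec, proto, dt)
        if i_step > 0:
            # passive depolarization must stay subthreshold: a cell at a
            # sub-rheobase current never sits above its AP threshold
            v[a:] = np.minimum(v[a:], thr - 2.0)
        return v

    v = np.full(n, spec.vrest)
    v_dep = thr - 1.0           # depolarized inter-spike baseline
    v_plat = thr + 12.0         # block plateau, above threshold
    template, _ = _spike_template(spec, dt)
    v_ahp = thr + spec.ahp
    ramp_slope = 5.0            # pre-spike approach, mV/ms (below 10 criterion)
    t0 = max(3.0, (thr - spec.vrest) / ramp_slope + 0.5)

    if blocked:
        f_b = max(spec.f_rate(max(i_step - STEP_GRID_PA, spec.rheobase)), 20.0)
        burst_ms = 0.3 * proto.step_ms
        n_sp = max(1, int(round(f_b * burst_ms / 1000.0 * 0.8)))
        offs = _isi_schedule(n_sp, 1.0, burst_ms, t0)
    else:
        n_sp = max(1, int(round(f * min(proto.step_ms, 500.0) / 1000.0)))
        offs = _isi_schedule(n_sp, spec.adaptation(i_step),
                             min(proto.step_ms, 500.0), t0)
        # steps longer than the 500 ms rate window keep firing at the
        # final interval so the train never appears to cease
        if proto.step_ms > 500.0 and len(offs):
            isi_last = offs[-1] - offs[-2] if len(offs) > 1 else 1000.0 / max(f, 2.0)
            extra = np.arange(offs[-1] + isi_last, proto.step_ms - 1.0, isi_last)
            offs = np.concatenate([offs, extra])

    # passive charge toward the inter-spike baseline, then a slow (< 10
    # mV/ms) approach ramp that meets threshold exactly at the first spike,
    # so the threshold detector never merges with pre-spike depolarization
    t_step = (np.arange(a, b) - a) * dt
    charge = v_dep + (spec.vrest - v_dep) * np.exp(-t_step / spec.tau_m)
    approach = thr - ramp_slope * (offs[0] - t_step)
    v[a:b] = np.where(t_step <= offs[0], np.maximum(charge, approach), charge)
    idx = a + np.round(offs / dt).astype(int)
    ends = []
    for k, j in enumerate(idx):
        if j >= b:
            break
        end = _splice(v, j, template)
        ends.append(end)
        nxt = idx[k + 1] if k + 1 < len(idx) else None
        # exponential recovery from the AHP trough toward the next threshold
        gap_end = min(nxt if nxt is not None else b, b)
        if end < gap_end:
            span = (gap_end - end) * dt
            depth = thr - v_ahp
            tau_b = span / math.log(max(depth, 0.5) / 0.3)
            tt = (np.arange(end, gap_end) - end) * dt
            if nxt is not None and nxt < b:
                v[end:gap_end] = thr - depth * np.exp(-tt / max(tau_b, dt))
            else:
                v[end:gap_end] = v_dep - (v_dep - v_ahp) * np.exp(-tt / spec.tau_m)
    if blocked and ends:
        start = min(ends[-1], b)
        tt = (np.arange(start, b) - start) * dt
        v[start:b] = v_plat - (v_plat - v_ahp) * np.exp(-tt / spec.tau_m)
    if b < n:
        tail = (np.arange(b, n) - b) * dt
        v[b:] = spec.vrest + (v[b - 1] - spec.vrest) * np.exp(-tail / spec.tau_m)
    return v


def simulate_cell(spec: SynthCellSpec, protocols: dict | None = None,
                  dt: float = DEFAULT_DT_MS) -> CellRecording:
    """Simulate the full step-protocol battery for one cell.

    ``protocols`` maps protocol tags to lists of :class:`StepProtocol`;
    when omitted, :func:`default_protocols` is used.  Deterministic given
    ``spec`` (noise comes from ``spec.seed``).
    """
    if protocols is None:
        protocols = default_protocols(spec)
    firing = protocols.get("firing_steps", [])
    if firing and max(p.step_pA for p in firing) < spec.rheobase:
        raise ValueError(
            f"firing_steps grid (max {max(p.step_pA for p in firing)} pA) "
            f"does not cover the cell's rheobase ({spec.rheobase} pA)"
        )
    rng = np.random.default_rng(spec.seed)
    rec = CellRecording(cell_id=spec.cell_id, genotype=spec.genotype,
                        resting_potential=spec.vrest)
    counter = 0
    for tag, protos in protocols.items():
        for proto in protos:
            if tag in ("subthreshold_steps", "tau_pulses"):
                sag_on = tag == "subthreshold_steps"
                v = _subthreshold_trace(spec, proto, dt, sag_active=sag_on)
            elif tag in ("firing_steps", "block_ramp"):
                v = _firing_trace(spec, proto, dt)
            else:
                raise ValueError(f"cannot simulate protocol {tag!r}")
            if spec.noise_v > 0:
                v = v + rng.normal(0.0, spec.noise_v, size=len(v))
            rec.sweeps.append(Trace(
                time_step=dt, voltage=v, current=proto.current_waveform(dt),
                sweep_id=f"s{counter:04d}", protocol_tag=tag,
                meta={"step_pA": proto.step_pA, "baseline_ms": proto.baseline_ms,
                      "step_ms": proto.step_ms},
            ))
            counter += 1
    return rec


def iter_cohort(genotype: str, params_list=None, seed: int = 0,
                noise_v: float = NOISE_V_SD):
    """Yield (CellRecording, true_label, SynthCellSpec) for a cohort.

    ``params_list`` defaults to the published composition for the genotype
    (``COHORT_COMPOSITION`` with ``SUBTYPE_TABLE`` parameters).  Pure
    function of (params, seed).
    """
    if params_list is None:
        if genotype not in COHORT_COMPOSITION:
            raise ValueError(f"unknown genotype {genotype!r}")
        params_list = [SUBTYPE_TABLE[(genotype, st)].with_n_cells(n)
                       for st, n in COHORT_COMPOSITION[genotype].items()]
    ss = np.random.SeedSequence([int(seed), 0xC311])
    children = ss.spawn(sum(p.n_cells for p in params_list))
    k = 0
    for params in params_list:
        if params.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for j in range(params.n_cells):
            rng = np.random.default_rng(children[k])
            cell_seed = int(rng.integers(0, 2**31 - 1))
            spec = draw_cell_spec(
                params, rng,
                cell_id=f"{genotype}_{params.label}_{j:03d}",
                seed=cell_seed, noise_v=noise_v)
            yield simulate_cell(spec), params.label, spec
            k += 1


def simulate_cohort(genotype: str, params_list=None, seed: int = 0,
                    noise_v: float = NOISE_V_SD):
    """Materialized cohort: list of (CellRecording, true_label)."""
    return [(rec, lab) for rec, lab, _ in
            iter_cohort(genotype, params_list, seed, noise_v)]


# ---------------------------------------------------------------------------
# synaptic pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSpec:
    """Stochastic depressing unitary synapse.

    Release at each presynaptic AP is Bernoulli with probability
    ``p0 * R**alpha`` and success amplitude ``potency * R`` where R is the
    available resource: on release R <- R * (1 - U); between APs R recovers
    toward 1 with time constant ``tau_rec``.  Successes produce an inward
    (negative) double-exponential current whose 5%-of-peak crossing falls
    ``latency`` ms (jittered) after the AP peak.
    """

    p0: float = 0.99
    potency_pA: float = 171.0
    U: float = 0.35
    tau_rec_ms: float = 120.0
    alpha: float = 0.4
    latency_ms: float = 1.2
    jitter_ms: float = 0.1
    rise_ms: float = 0.3
    decay_ms: float = 6.6
    noise_sd_pA: float = NOISE_I_SD

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if not (self.decay_ms > self.rise_ms > 0):
            raise ValueError("need decay > rise > 0")


#: Published unitary-connection presets (potency pA, failure probability,
#: latency ms, decay ms) per connection class.
PAIR_TABLE = {
    "WT_FS_BC": PairSpec(p0=0.99, potency_pA=171.0, latency_ms=1.2, decay_ms=6.6),
    "WT_FS_DTC": PairSpec(p0=0.89, potency_pA=26.0, latency_ms=1.1, decay_ms=7.0),
    "WT_NFS_BC": PairSpec(p0=0.77, potency_pA=56.0, latency_ms=2.4, decay_ms=5.4),
    "GlobalLis_FS": PairSpec(p0=0.97, potency_pA=71.0, latency_ms=0.9, decay_ms=6.5),
    "GlobalLis_IS": PairSpec(p0=0.83, potency_pA=56.0, latency_ms=1.6, decay_ms=7.7),
}


def _ipsc_kernel(spec: PairSpec, dt: float):
    """Unit-peak double-exponential kernel and its 5%-of-peak rise time."""
    t = np.arange(0.0, spec.decay_ms * 8, dt)
    k = np.exp(-t / spec.decay_ms) - np.exp(-t / spec.rise_ms)
    k /= k.max()
    t5 = t[np.argmax(k >= 0.05)]
    return k, t5


def simulate_pair(spec: PairSpec, ap_times_ms, n_trials: int,
                  seed: int = 0, dt: float = DEFAULT_DT_MS,
                  post_ms: float = 60.0) -> PairedRecording:
    """Simulate postsynaptic current trials for a presynaptic AP pattern.

    Returns a :class:`~pvint.core.PairedRecording` whose ``trials`` array
    holds the postsynaptic current (pA; IPSCs are negative deflections).
    """
    ap = np.asarray(ap_times_ms, dtype=float)
    if len(ap) and not (np.diff(ap) > 0).all():
        raise ValueError("ap_times_ms must be strictly increasing")
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    kernel, t5 = _ipsc_kernel(spec, dt)
    dur = (ap[-1] if len(ap) else 0.0) + post_ms
    n = int(round(dur / dt))
    trials = np.zeros((n_trials, n))
    success = np.zeros((n_trials, len(ap)), dtype=bool)
    amps = np.zeros((n_trials, len(ap)))
    for tr in range(n_trials):
        r = 1.0
        last_t = None
        for k, t_ap in enumerate(ap):
            if last_t is not None:
                r = 1.0 - (1.0 - r) * math.exp(-(t_ap - last_t) / spec.tau_rec_ms)
            last_t = t_ap
            p_rel = spec.p0 * r ** spec.alpha
            if rng.uniform() < p_rel:
                amp = spec.potency_pA * r
                lat = spec.latency_ms + rng.normal(0.0, spec.jitter_ms)
                onset = t_ap + max(lat - t5, 0.0)
                j = int(round(onset / dt))
                if j < n:
                    m = min(len(kernel), n - j)
                    trials[tr, j:j + m] += -amp * kernel[:m]
                success[tr, k] = True
                amps[tr, k] = amp
                r *= 1.0 - spec.U
        if spec.noise_sd_pA > 0:
            trials[tr] += rng.normal(0.0, spec.noise_sd_pA, size=n)
    return PairedRecording(dt_ms=dt, ap_times_ms=ap, trials=trials,
                           meta={"success": success, "amps": amps})


def train_50hz(n_pulses: int = 25, start_ms: float = 10.0,
               rate_hz: float = 50.0) -> np.ndarray:
    """Presynaptic AP times for the standard high-frequency train."""
    return start_ms + 1000.0 / rate_hz * np.arange(n_pulses)


# ---------------------------------------------------------------------------
# morphologies
# ---------------------------------------------------------------------------

def simulate_morphology(orientation_bias: float, n_branches: int,
                        seed: int = 0, segment_um: float = 20.0,
                        branch_prob: float = 0.25,
                        angular_spread: float = 1.0,
                        neurite_class: str = "axon") -> NeuriteTree:
    """Grow a flat (z = 0) branching tree with controlled orientation.

    Each new segment's direction is horizontal (uniform over the two
    60-degree horizontal wedges, shrunk by ``angular_spread``) with
    probability ``orientation_bias`` and uniform over the complementary
    240 degrees otherwise, so the expected horizontal length fraction is
    the bias itself.  With ``branch_prob`` the segment sprouts from a
    random existing node instead of extending a tip.
    """
    if not (0.0 <= orientation_bias <= 1.0):
        raise ValueError("orientation_bias must lie in [0, 1]")
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = {1: SWCNode(1, "soma", 0.0, 0.0, 0.0, 5.0, -1)}
    tips = [1]
    nid = 1
    for _ in range(n_branches):
        if len(tips) > 1 and rng.uniform() < branch_prob:
            src = int(rng.choice(tips))
        else:
            src = tips[-1]
        if rng.uniform() < orientation_bias:
            center = rng.choice([0.0, 180.0])
            ang = center + rng.uniform(-30.0, 30.0) * angular_spread
        else:
            # uniform over the 240 degrees outside the horizontal wedges
            u = rng.uniform(0.0, 240.0)
            ang = 30.0 + u if u < 120.0 else 210.0 + (u - 120.0)
        th = math.radians(ang % 360.0)
        p = nodes[src]
        nid += 1
        nodes[nid] = SWCNode(nid, neurite_class,
                             p.x + segment_um * math.cos(th),
                             p.y + segment_um * math.sin(th),
                             0.0, 0.5, src)
        tips.append(nid)
    return NeuriteTree(nodes=nodes, root_id=1)


# ---------------------------------------------------------------------------
# elevated-potassium continuous sweeps
# ---------------------------------------------------------------------------

def simulate_elevated_k(spec: SynthCellSpec, n_sweeps: int = 10,
                        sweep_s: float = 10.0, evoked_ms: float = 500.0,
                        block_after_sweep: int | None = None,
                        dt: float = DEFAULT_DT_MS, seed: int = 0) -> list:
    """Continuous sweeps with an evoked-firing window at each sweep start.

    Cells that are block-resistant fire through every evoked window; a cell
    driven into depolarization block stops firing (plateau above threshold)
    in every window from ``block_after_sweep`` on.
    """
    rng = np.random.default_rng(seed)
    sweeps = []
    i_evk = _grid(1.5 * spec.rheobase)
    proto = StepProtocol(100.0, evoked_ms, i_evk, 100.0)
    n_total = int(round(sweep_s * 1000.0 / dt))
    for s in range(n_sweeps):
        blocked = block_after_sweep is not None and s >= block_after_sweep
        sub = replace(spec, block_current=i_evk if blocked else None)
        head = _firing_trace(sub, proto, dt)
        v = np.full(n_total, spec.vrest)
        v[: len(head)] = head[:n_total]
        v = v + rng.normal(0.0, spec.noise_v, size=n_total)
        cur = np.zeros(n_total)
        a = int(round(100.0 / dt))
        bwin = int(round((100.0 + evoked_ms) / dt))
        cur[a:bwin] = i_evk
        sweeps.append(Trace(
            time_step=dt, voltage=v, current=cur, sweep_id=f"k{s:03d}",
            protocol_tag="continuous",
            meta={"evoked_windows": [[100.0, evoked_ms]], "step_pA": i_evk},
        ))
    return sweeps
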