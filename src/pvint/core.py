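"""Domain types and unit conventions shared by every analysis stage.

Canonical units, fixed package-wide: voltage mV, current pA, time ms,
resistance MOhm, capacitance pF, rate Hz.  Converters live at the I/O
boundary only; everything downstream of the readers assumes these units.

Sampling is uniform.  Derivative-based measures (the 10 mV/ms action
potential threshold criterion in particular) are sensitive to the sample
grid, so traces with non-uniform timestamps are rejected at load rather
than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Protocol vocabulary.  Every sweep carries exactly one of these tags.
PROTOCOL_TAGS = (
    "subthreshold_steps",
    "tau_pulses",
    "firing_steps",
    "block_ramp",
    "continuous",
    "postsynaptic",
)

GENOTYPES = ("WT", "GlobalLis", "NkxLis", "EmxLis")
LAYERS = ("so", "sp", "sr", "slm", "unknown")
SUBTYPES = ("FS", "IS", "NFS")

#: Default sampling interval, ms (20 kHz acquisition).
DEFAULT_DT_MS = 0.05


class FormatError(ValueError):
    """Raised when an on-disk container violates the sweep-file contract."""


class InsufficientDataError(ValueError):
    """Raised when a feature cannot be computed from the sweeps provided."""


@dataclass
class Trace:
    """A single current-clamp or voltage-clamp sweep.

    Parameters
    ----------
    time_step : float
        Sample interval in ms (uniform).
    voltage : ndarray
        Membrane voltage in mV.
    current : ndarray
        Command (or recorded) current in pA; same length as ``voltage``.
    sweep_id : str
        Identifier unique within the parent recording.
    protocol_tag : str
        One of :data:`PROTOCOL_TAGS`.
    meta : dict
        Protocol metadata: ``step_pA``, ``baseline_ms``, ``step_ms`` for
        step protocols; ``evoked_windows`` (list of (start_ms, dur_ms))
        for continuous sweeps; ``ap_peaks_ms`` for postsynaptic sweeps.
    """

    time_step: float
    voltage: np.ndarray
    current: np.ndarray
    sweep_id: str = "sweep"
    protocol_tag: str = "firing_steps"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time_step <= 0:
            raise ValueError(f"time_step must be > 0, got {self.time_step}")
        if self.voltage.ndim != 1 or self.current.ndim != 1:
            raise ValueError("voltage and current must be 1-D")
        if len(self.voltage) != len(self.current):
            raise ValueError(
                f"sweep {self.sweep_id!r}: voltage length {len(self.voltage)} "
                f"!= current length {len(self.current)}"
            )
        if len(self.voltage) < 2:
            raise ValueError(f"sweep {self.sweep_id!r}: need >= 2 samples")
        if not (np.isfinite(self.voltage).all() and np.isfinite(self.current).all()):
            raise ValueError(f"sweep {self.sweep_id!r}: non-finite samples")
        if self.protocol_tag not in PROTOCOL_TAGS:
            raise ValueError(f"unknown protocol_tag {self.protocol_tag!r}")

    @property
    def n_samples(self) -> int:
        return len(self.voltage)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.time_step

    @property
    def t_ms(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n_samples) * self.time_step

    @property
    def step_pA(self) -> Optional[float]:
        return self.meta.get("step_pA")


@dataclass(frozen=True)
class StepProtocol:
    """A rectangular current-step stimulus."""

    baseline_ms: float
    step_ms: float
    step_pA: float
    post_ms: float

    def __post_init__(self) -> None:
        if not (100.0 <= self.step_ms <= 2000.0):
            raise ValueError(f"step_ms must lie in [100, 2000], got {self.step_ms}")
        if self.baseline_ms < 50.0:
            raise ValueError(f"baseline_ms must be >= 50, got {self.baseline_ms}")
        if self.post_ms < 0:
            raise ValueError("post_ms must be >= 0")

    @property
    def total_ms(self) -> float:
        return self.baseline_ms + self.step_ms + self.post_ms

    def current_waveform(self, dt_ms: float) -> np.ndarray:
        n = int(round(self.total_ms / dt_ms))
        i = np.zeros(n)
        a = int(round(self.baseline_ms / dt_ms))
        b = int(round((self.baseline_ms + self.step_ms) / dt_ms))
        i[a:b] = self.step_pA
        return i


@dataclass
class CellRecording:
    """All sweeps recorded from one cell, grouped by protocol."""

    cell_id: str
    genotype: str = "WT"
    layer: str = "unknown"
    sweeps: list = field(default_factory=list)
    resting_potential: float = -65.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    def by_protocol(self, tag: str) -> list:
        """Sweeps with the given tag, sorted by step amplitude."""
        if tag not in PROTOCOL_TAGS:
            raise ValueError(f"unknown protocol_tag {tag!r}")
        sel = [s for s in self.sweeps if s.protocol_tag == tag]
        return sorted(sel, key=lambda s: (s.meta.get("step_pA", 0.0), s.sweep_id))

    def sorted_sweeps(self) -> list:
        """All sweeps, sorted by protocol tag order then step amplitude."""
        order = {t: i for i, t in enumerate(PROTOCOL_TAGS)}
        return sorted(
            self.sweeps,
            key=lambda s: (order[s.protocol_tag], s.meta.get("step_pA", 0.0), s.sweep_id),
        )


@dataclass
class PairedRecording:
    """A paired-recording block: presynaptic AP peak times plus repeated
    postsynaptic current trials (pA), all trials sharing one time base."""

    dt_ms: float
    ap_times_ms: np.ndarray
    trials: np.ndarray  # (n_trials, n_samples)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ap_times_ms = np.asarray(self.ap_times_ms, dtype=float)
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


@dataclass
class CompositionTable:
    """Counts of physiological subtypes per genotype."""

    genotypes: list
    subtypes: list
    counts: np.ndarray  # shape (len(genotypes), len(subtypes))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.genotypes), len(self.subtypes)):
            raise ValueError("counts shape does not match row/column labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def percentages(self) -> np.ndarray:
        """Row percentages, nearest-integer rounded.  Empty rows are zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        pct = np.where(totals > 0, pct, 0.0)
        return np.rint(pct).astype(int)

    def percentages_exact(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.where(totals > 0, pct, 0.0)


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31.

    Uses a CRC of the stage name mixed with the base seed so that editing
    one stage's configuration does not shift another stage's stream.
    """
    import zlib

    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
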