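"""Core domain types shared across the package.

Conventions: times in seconds, voltages in microvolts, angles in radians
wrapped to (-pi, pi] under the cosine convention (0 = peak, pi = trough).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circular import wrap_phase

CONDITIONS = ("no_stim", "peak", "trough", "random")


@dataclass
class ContinuousSignal:
    """Uniformly sampled voltage trace.

    Attributes
    ----------
    samples : ndarray, microvolts
    sampling_rate : float, Hz
    start_time : float, seconds (time of the first sample)
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def slice(self, t0: float, t1: float) -> "ContinuousSignal":
        """Sub-signal covering [t0, t1) (sample-aligned)."""
        i0 = max(0, int(round((t0 - self.start_time) * self.sampling_rate)))
        i1 = min(self.n_samples, int(round((t1 - self.start_time) * self.sampling_rate)))
        if i1 <= i0:
            raise ValueError("empty slice")
        return ContinuousSignal(
            self.samples[i0:i1], self.sampling_rate, self.start_time + i0 / self.sampling_rate
        )


@dataclass
class BandSpec:
    """Target oscillation band for phase estimation.

    ``n_cycles`` sets the Morlet kernel width (temporal SD =
    n_cycles / (2*pi*center_frequency)); ``passband`` is the zero-phase
    filter range used by the offline oracle and as the clamp for
    instantaneous-frequency estimates.
    """

    center_frequency: float
    n_cycles: float = 7.0
    passband: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center_frequency must be positive")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")
        if self.passband is None:
            f = self.center_frequency
            self.passband = (max(0.5, f * 0.75), f * 1.5)
        lo, hi = self.passband
        if not (0 < lo < self.center_frequency < hi):
            raise ValueError("passband must bracket center_frequency")


def band_4hz() -> BandSpec:
    """Default low-frequency (~4 Hz) striatal band."""
    return BandSpec(center_frequency=4.0, n_cycles=4.0, passband=(3.0, 8.0))


def band_20hz() -> BandSpec:
    """Default beta (~20 Hz) band."""
    return BandSpec(center_frequency=20.0, n_cycles=7.0, passband=(16.0, 25.0))


@dataclass
class PhaseEstimate:
    """Instantaneous phase/frequency/amplitude of one band at one time.

    ``phase_defined`` is False when the wavelet amplitude is numerically zero
    (e.g. an all-zero window); a controller must not fire on such estimates.
    """

    time: float
    phase: float
    frequency: float
    amplitude: float
    phase_defined: bool = True

    def __post_init__(self) -> None:
        if self.phase_defined:
            self.phase = wrap_phase(self.phase)
            if not np.isfinite(self.phase) or not np.isfinite(self.frequency):
                raise ValueError("phase and frequency must be finite")
            if self.frequency <= 0:
                raise ValueError("frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class LatencyModel:
    """Additive latency budget of the closed loop, milliseconds per stage."""

    acquisition_ms: float = 0.0
    buffer_ms: float = 10.0
    compute_ms: float = 2.05
    transport_ms: float = 0.21
    actuator_rise_ms: float = 0.74

    def __post_init__(self) -> None:
        for name in ("acquisition_ms", "buffer_ms", "compute_ms", "transport_ms", "actuator_rise_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_ms(self) -> float:
        return (
            self.acquisition_ms
            + self.buffer_ms
            + self.compute_ms
            + self.transport_ms
            + self.actuator_rise_ms
        )


@dataclass
class StimulationPolicy:
    """When to fire: band, target phase, tolerance, refractory, gating.

    ``target_phase`` is radians, or the string ``"random"`` for the
    phase-random control (Bernoulli firing matched in expected rate).
    ``refractory_s`` defaults to half the target period, bounding the pulse
    rate near the band frequency.
    """

    band: BandSpec
    target_phase: float | str = 0.0
    phase_tolerance: float = 0.3
    refractory_s: float | None = None
    pulse_width_ms: float = 5.0
    amplitude_gate: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.target_phase, str):
            if self.target_phase != "random":
                raise ValueError('target_phase must be radians or "random"')
        else:
            self.target_phase = wrap_phase(float(self.target_phase))
        if not (0 < self.phase_tolerance <= np.pi):
            raise ValueError("phase_tolerance must be in (0, pi]")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.refractory_s is None:
            self.refractory_s = 0.5 / self.band.center_frequency
        if self.refractory_s < self.pulse_width_ms / 1000.0:
            raise ValueError("refractory_s must be >= pulse width")
        if self.amplitude_gate < 0:
            raise ValueError("amplitude_gate must be >= 0")


@dataclass
class StimulationEvent:
    """One commanded pulse; ``true_phase_at_delivery`` is filled offline."""

    command_time: float
    delivery_time: float
    pulse_width_ms: float
    target_phase: float
    predicted_phase_at_delivery: float
    true_phase_at_delivery: float = float("nan")

    def __post_init__(self) -> None:
        if self.delivery_time < self.command_time:
            raise ValueError("delivery_time must be >= command_time")
        self.target_phase = wrap_phase(self.target_phase)
        self.predicted_phase_at_delivery = wrap_phase(self.predicted_phase_at_delivery)
        if np.isfinite(self.true_phase_at_delivery):
            self.true_phase_at_delivery = wrap_phase(self.true_phase_at_delivery)


@dataclass
class PhaseAccuracyResult:
    """Achieved-phase accuracy of a stimulation session.

    ``phase_differences`` are wrap(true phase at delivery - target phase);
    ``circular_average`` is the argument of their mean resultant vector and
    ``dispersion_interval`` the circular (Q1, Q3) around it.
    """

    phase_differences: np.ndarray
    circular_average: float
    dispersion_interval: tuple[float, float]
    n_events: int

    def __post_init__(self) -> None:
        self.phase_differences = np.asarray(self.phase_differences, dtype=float)
        if self.n_events != self.phase_differences.size:
            raise ValueError("n_events must equal the number of differences")


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (seconds) of one unit."""

    spike_times: np.ndarray
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class HeadTrajectory:
    """3-D head position track at a uniform frame rate (mm, seconds)."""

    timestamps: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        if self.timestamps.size != self.positions.shape[0]:
            raise ValueError("timestamps and positions length mismatch")
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            # tolerate microsecond quantization from CSV round trips
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=2.1e-6):
                raise ValueError("timestamps must be uniformly spaced")
            if dt[0] <= 0:
                raise ValueError("timestamps must be increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def frame_rate(self) -> float:
        if self.timestamps.size < 2:
            raise ValueError("frame rate undefined for < 2 frames")
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    @property
    def n_frames(self) -> int:
        return self.timestamps.size


@dataclass
class Epoch:
    start: float
    end: float
    condition: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


@dataclass
class EpochSet:
    """Non-overlapping labeled condition epochs (default 30 s each)."""

    epochs: list[Epoch]
    epoch_duration: float = 30.0

    def __post_init__(self) -> None:
        ordered = sorted(self.epochs, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping epochs: ({a.start}, {a.end}, {a.condition}) and "
                    f"({b.start}, {b.end}, {b.condition})"
                )
        self.epochs = ordered

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def span(self) -> tuple[float, float]:
        return self.epochs[0].start, self.epochs[-1].end


@dataclass
class SpectrumResult:
    """One-sided power spectral density (uV^2/Hz) on a monotone grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids must match")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class CoherenceResult:
    """Spike-field coherence per frequency; NaN marks indeterminate values
    (too few windows containing spikes), never silently zero."""

    frequencies: np.ndarray
    coherence: np.ndarray
    n_windows_used: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        if self.frequencies.shape != self.coherence.shape:
            raise ValueError("frequency and coherence grids must match")
        defined = self.coherence[np.isfinite(self.coherence)]
        if defined.size and (np.any(defined < 0) or np.any(defined > 1 + 1e-9)):
            raise ValueError("defined coherence values must lie in [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.coherence)

    def at(self, frequency: float) -> float:
        """Coherence at the grid point nearest ``frequency`` (NaN if undefined)."""
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        return float(self.coherence[i])


@dataclass
class EpochComparison:
    """Nonparametric contrast of per-session values across conditions."""

    per_session_values: dict[str, np.ndarray]
    medians_and_iqr: dict[str, tuple[float, float, float]]
    compared_conditions: tuple[str, str]
    rank_sum_p: float
    cohens_d: float
    percent_change: float

    def __post_init__(self) -> None:
        if not (0 <= self.rank_sum_p <= 1):
            raise ValueError("p-value must be in [0, 1]")
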