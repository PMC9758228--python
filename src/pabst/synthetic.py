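"""Synthetic data with the statistical structure the method assumes.

The local field potential (LFP) model is a sum of narrow-band oscillators
whose instantaneous frequency performs a bounded random walk (the
nonstationarity a forward phase predictor must handle), embedded in
1/f**exponent Gaussian noise. Spiking is an inhomogeneous Poisson process
with von Mises phase tuning; stimulation-evoked spikes are inserted at a
short fixed latency. Head trajectories are smooth correlated random walks
whose expected speed is scaled per condition epoch.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .types import ContinuousSignal, EpochSet, HeadTrajectory, SpikeTrain, StimulationEvent

__all__ = [
    "OscillatorSpec",
    "NoiseSpec",
    "SpikeGenSpec",
    "MotionSpec",
    "SyntheticLFP",
    "generate_lfp",
    "generate_phase_locked_spikes",
    "apply_evoked_spikes",
    "generate_head_trajectory",
]


@dataclass
class OscillatorSpec:
    """One band-limited oscillator.

    ``frequency_jitter_sd`` is the SD (Hz) of the frequency random walk over
    one second; the walk is reflected at ``center_frequency +/-
    max_frequency_deviation`` so the oscillator stays inside its analysis
    band. ``amplitude_jitter_sd`` is the fractional SD of a slow (~1 s)
    amplitude modulation. ``initial_phase`` of None draws a uniform phase.
    """

    center_frequency: float
    amplitude: float = 1.0
    frequency_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0
    max_frequency_deviation: float | None = None
    initial_phase: float | None = 0.0

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center_frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency_jitter_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.max_frequency_deviation is None:
            self.max_frequency_deviation = min(self.center_frequency / 2.0, 4.0)
        if not 0 < self.max_frequency_deviation < self.center_frequency:
            raise ValueError("max_frequency_deviation must be in (0, center_frequency)")


@dataclass
class NoiseSpec:
    """Background 1/f**exponent Gaussian noise; ``scale`` is its SD (uV)."""

    exponent: float = 1.0
    scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.exponent <= 3:
            raise ValueError("exponent must be in [0, 3]")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


@dataclass
class SpikeGenSpec:
    """Phase-locked point process with optional stimulus-evoked spikes.

    Intensity: base_rate * exp(kappa*cos(phase - preferred)) / I0(kappa),
    which integrates to base_rate over a full cycle. Evoked spikes follow a
    pulse with probability ``evoked_probability`` at ``evoked_latency_ms``.
    """

    base_rate: float = 5.0
    locking_concentration: float = 0.0
    preferred_phase: float = 0.0
    evoked_probability: float = 0.0
    evoked_latency_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.locking_concentration < 0:
            raise ValueError("locking_concentration must be non-negative")
        if not -np.pi < self.preferred_phase <= np.pi:
            raise ValueError("preferred_phase must be in (-pi, pi]")
        if not 0 <= self.evoked_probability <= 1:
            raise ValueError("evoked_probability must be in [0, 1]")
        if self.evoked_latency_ms < 0:
            raise ValueError("evoked_latency_ms must be non-negative")


@dataclass
class MotionSpec:
    """Head-trajectory generator parameters.

    ``condition_speed_multipliers`` maps epoch condition labels to speed
    scale factors; ``smoothness`` is the correlation time (s) of the
    velocity direction and of the speed fluctuations (CV ``speed_cv``).
    """

    frame_rate: float = 120.0
    baseline_speed: float = 20.0
    condition_speed_multipliers: dict[str, float] = field(
        default_factory=lambda: {"no_stim": 1.0, "peak": 0.93, "trough": 1.4, "random": 1.0}
    )
    smoothness: float = 0.5
    speed_cv: float = 0.2

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.baseline_speed < 0:
            raise ValueError("baseline_speed must be non-negative")
        if any(m <= 0 for m in self.condition_speed_multipliers.values()):
            raise ValueError("speed multipliers must be positive")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if self.speed_cv < 0:
            raise ValueError("speed_cv must be non-negative")


@dataclass
class SyntheticLFP:
    """Generated LFP plus the per-oscillator ground truth that produced it."""

    signal: ContinuousSignal
    phases: list[np.ndarray]
    frequencies: list[np.ndarray]

    def phase_trace(self, i: int = 0) -> np.ndarray:
        """Unwrapped ground-truth phase of oscillator ``i``."""
        return self.phases[i]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _one_over_f_noise(n: int, exponent: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if exponent == 0:
        return scale * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    colored = np.fft.irfft(spec * shape, n=n)
    sd = colored.std()
    return scale * colored / sd if sd > 0 else colored


def _ou_process(n: int, dt: float, tau: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    alpha = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1 - alpha**2)
    steps = rng.standard_normal(n - 1) * innov_sd
    for i in range(1, n):
        x[i] = alpha * x[i - 1] + steps[i - 1]
    return x


def generate_lfp(
    oscillators: list[OscillatorSpec],
    noise: NoiseSpec,
    duration: float,
    sampling_rate: float,
    seed: int,
) -> SyntheticLFP:
    """Simulate an LFP record and return it with ground-truth phase traces.

    Parameters
    ----------
    duration : seconds; the output has exactly round(duration*sampling_rate)
        samples.
    sampling_rate : Hz; must be at least 4x the fastest oscillator.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if oscillators:
        fmax = max(o.center_frequency for o in oscillators)
        if sampling_rate < 4 * fmax:
            raise ValueError(
                f"sampling_rate {sampling_rate} Hz is below 4x the fastest "
                f"oscillator ({fmax} Hz)"
            )
    n = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    rng = np.random.default_rng(seed)

    samples = np.zeros(n)
    phases: list[np.ndarray] = []
    freqs_out: list[np.ndarray] = []
    for osc in oscillators:
        if osc.frequency_jitter_sd > 0:
            walk = np.cumsum(rng.standard_normal(n) * osc.frequency_jitter_sd * np.sqrt(dt))
            freq = _reflect(
                osc.center_frequency + walk,
                osc.center_frequency - osc.max_frequency_deviation,
                osc.center_frequency + osc.max_frequency_deviation,
            )
        else:
            freq = np.full(n, osc.center_frequency)
        phi0 = rng.uniform(-np.pi, np.pi) if osc.initial_phase is None else float(osc.initial_phase)
        # phase-continuous integration; phase[k] is the phase at sample k
        phase = phi0 + 2 * np.pi * dt * np.concatenate(([0.0], np.cumsum(freq[:-1])))
        if osc.amplitude_jitter_sd > 0:
            mod = _ou_process(n, dt, 1.0, osc.amplitude_jitter_sd, rng)
            amp = osc.amplitude * np.maximum(0.0, 1.0 + mod)
        else:
            amp = osc.amplitude
        samples += amp * np.cos(phase)
        phases.append(phase)
        freqs_out.append(freq)

    samples += _one_over_f_noise(n, noise.exponent, noise.scale, rng)
    sig = ContinuousSignal(samples, sampling_rate, start_time=0.0)
    return SyntheticLFP(signal=sig, phases=phases, frequencies=freqs_out)


def generate_phase_locked_spikes(
    phase_trace: np.ndarray,
    sampling_rate: float,
    spec: SpikeGenSpec,
    seed: int,
    start_time: float = 0.0,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Draw an inhomogeneous Poisson spike train locked to a phase trace.

    Uses thinning against the peak intensity
    base_rate * exp(kappa) / I0(kappa); spike times are strictly increasing.
    """
    phase_trace = np.asarray(phase_trace, dtype=float)
    if phase_trace.size == 0:
        raise ValueError("phase trace must be non-empty")
    if not np.all(np.isfinite(phase_trace)):
        raise ValueError("phase trace must be finite")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if spec.base_rate == 0:
        return SpikeTrain(np.empty(0), unit_id=unit_id)

    rng = np.random.default_rng(seed)
    duration = phase_trace.size / sampling_rate
    kappa = spec.locking_concentration
    lam_max = spec.base_rate * np.exp(kappa) / i0(kappa)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    phi = np.interp(cand, np.arange(phase_trace.size) / sampling_rate, phase_trace)
    accept_p = np.exp(kappa * (np.cos(phi - spec.preferred_phase) - 1.0))
    keep = rng.uniform(size=n_cand) < accept_p
    times = start_time + cand[keep]
    times = np.unique(times)  # guard against duplicate uniforms
    return SpikeTrain(times, unit_id=unit_id)


def apply_evoked_spikes(
    spikes: SpikeTrain,
    events: list[StimulationEvent],
    spec: SpikeGenSpec,
    seed: int,
) -> SpikeTrain:
    """Insert stimulus-evoked spikes after each pulse.

    Each event evokes one extra spike at delivery_time + evoked_latency_ms
    with probability evoked_probability; output stays sorted and unique.
    """
    rng = np.random.default_rng(seed)
    extra = []
    for ev in events:
        if rng.uniform() < spec.evoked_probability:
            extra.append(ev.delivery_time + spec.evoked_latency_ms / 1000.0)
    merged = np.unique(np.concatenate([spikes.spike_times, np.asarray(extra, dtype=float)]))
    return SpikeTrain(merged, unit_id=spikes.unit_id)


def generate_head_trajectory(epochs: EpochSet, spec: MotionSpec, seed: int) -> HeadTrajectory:
    """Simulate a 3-D head track over the span of ``epochs``.

    Speed is baseline_speed * multiplier(condition of the current epoch)
    modulated by a smooth positive process (CV = speed_cv); the velocity
    direction performs a correlated random walk on the unit sphere with
    correlation time ``smoothness``. Frames outside any epoch use
    multiplier 1.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = epochs.span
    dt = 1.0 / spec.frame_rate
    n = int(round((t1 - t0) * spec.frame_rate)) + 1
    t = t0 + np.arange(n) * dt

    mult = np.ones(n)
    for ep in epochs:
        m = spec.condition_speed_multipliers.get(ep.condition, 1.0)
        mult[(t >= ep.start) & (t < ep.end)] = m
    target_speed = spec.baseline_speed * mult

    speed_mod = np.maximum(0.0, 1.0 + _ou_process(n, dt, spec.smoothness, spec.speed_cv, rng))
    speed = target_speed * speed_mod

    # correlated random walk of the heading on the unit sphere
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    sigma_step = np.sqrt(dt / spec.smoothness)
    steps = rng.standard_normal((n, 3)) * sigma_step
    headings = np.empty((n, 3))
    for i in range(n):
        u = u + steps[i]
        u /= np.linalg.norm(u)
        headings[i] = u

    # position increments reproduce the commanded per-frame speed exactly
    disp = headings[:-1] * (speed[:-1] * dt)[:, None]
    positions = np.vstack([np.zeros(3), np.cumsum(disp, axis=0)])
    return HeadTrajectory(timestamps=t, positions=positions)
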