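"""Run configuration: one YAML file drives the whole pipeline.

The default configuration encodes the study conditions the package
simulates: a 4 Hz target rhythm (plus a 20 Hz beta bystander) in 1/f
noise at amplitude-SNR 2, six sessions of three 30-s condition epochs
(no_stim / peak / trough), the measured latency budget, phase-locked
spiking with stimulus-evoked responses, and 120 frames/s head tracking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import MotionSpec, NoiseSpec, OscillatorSpec, SpikeGenSpec
from .types import BandSpec, LatencyModel, StimulationPolicy


@dataclass
class RunConfig:
    """Parsed, validated configuration for simulate/run/analyze pipelines."""

    seed: int = 1
    sampling_rate: float = 1000.0
    session_duration: float = 90.0
    n_sessions: int = 6
    epoch_duration: float = 30.0
    epoch_conditions: list[str] = field(default_factory=lambda: ["no_stim", "peak", "trough"])
    band: BandSpec = field(default_factory=lambda: BandSpec(4.0, 4.0, (3.0, 8.0)))
    oscillators: list[OscillatorSpec] = field(
        default_factory=lambda: [
            OscillatorSpec(4.0, amplitude=1.0, frequency_jitter_sd=0.3),
            OscillatorSpec(20.0, amplitude=0.5, frequency_jitter_sd=0.5),
        ]
    )
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(exponent=1.0, scale=0.5))
    spikes: SpikeGenSpec = field(
        default_factory=lambda: SpikeGenSpec(
            base_rate=5.0,
            locking_concentration=2.0,
            preferred_phase=3.141592653589793,
            evoked_probability=0.6,
            evoked_latency_ms=3.0,
        )
    )
    motion: MotionSpec = field(default_factory=MotionSpec)
    phase_tolerance: float = 0.3
    pulse_width_ms: float = 5.0
    amplitude_gate: float = 0.0
    latency: LatencyModel = field(default_factory=LatencyModel)

    def policy(self, target_phase) -> StimulationPolicy:
        return StimulationPolicy(
            band=self.band,
            target_phase=target_phase,
            phase_tolerance=self.phase_tolerance,
            pulse_width_ms=self.pulse_width_ms,
            amplitude_gate=self.amplitude_gate,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    """Invalid configuration file or values."""


def _build(cls, data: dict, context: str):
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, falling back to defaults for absent sections."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    scalars = (
        "seed",
        "sampling_rate",
        "session_duration",
        "n_sessions",
        "epoch_duration",
        "epoch_conditions",
        "phase_tolerance",
        "pulse_width_ms",
        "amplitude_gate",
    )
    for key in scalars:
        if key in raw:
            kwargs[key] = raw[key]
    if "band" in raw:
        band = dict(raw["band"])
        if "passband" in band and band["passband"] is not None:
            band["passband"] = tuple(band["passband"])
        kwargs["band"] = _build(BandSpec, band, "band")
    if "oscillators" in raw:
        kwargs["oscillators"] = [
            _build(OscillatorSpec, o, "oscillator") for o in raw["oscillators"]
        ]
    if "noise" in raw:
        kwargs["noise"] = _build(NoiseSpec, dict(raw["noise"]), "noise")
    if "spikes" in raw:
        kwargs["spikes"] = _build(SpikeGenSpec, dict(raw["spikes"]), "spikes")
    if "motion" in raw:
        kwargs["motion"] = _build(MotionSpec, dict(raw["motion"]), "motion")
    if "latency" in raw:
        kwargs["latency"] = _build(LatencyModel, dict(raw["latency"]), "latency")
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_default_config(path: str | Path) -> None:
    """Write the default configuration as a commented-free YAML file."""
    cfg = RunConfig()
    data = cfg.to_dict()
    data["band"]["passband"] = list(data["band"]["passband"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
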