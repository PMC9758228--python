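"""File formats: flat int16 binary + JSON sidecar for signals, CSV for
spikes, events, trajectories, and epochs.

All times are seconds written at microsecond precision; readers validate
the type invariants (lengths, sortedness, non-overlap) and fail with errors
that name the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ContinuousSignal,
    Epoch,
    EpochSet,
    HeadTrajectory,
    SpikeTrain,
    StimulationEvent,
)

__all__ = [
    "write_signal",
    "read_signal",
    "write_spikes",
    "read_spikes",
    "write_events",
    "read_events",
    "write_trajectory",
    "read_trajectory",
    "write_epochs",
    "read_epochs",
]

_SIGNAL_DTYPE = "<i2"  # little-endian 16-bit integers


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal(
    signal: ContinuousSignal,
    path: str | Path,
    gain_uV_per_bit: float | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a signal as little-endian int16 plus a JSON sidecar.

    ``gain_uV_per_bit`` defaults to max|sample|/32000 so the full range is
    used; the round trip is lossless up to one quantization step.
    """
    path = Path(path)
    if gain_uV_per_bit is None:
        peak = float(np.max(np.abs(signal.samples))) if signal.n_samples else 0.0
        gain_uV_per_bit = peak / 32000.0 if peak > 0 else 1.0
    if gain_uV_per_bit <= 0:
        raise ValueError("gain_uV_per_bit must be positive")
    quantized = np.clip(np.round(signal.samples / gain_uV_per_bit), -32768, 32767)
    quantized.astype(_SIGNAL_DTYPE).tofile(path)
    sidecar = {
        "sampling_rate_hz": signal.sampling_rate,
        "start_time_s": signal.start_time,
        "gain_uV_per_bit": gain_uV_per_bit,
        "n_samples": int(signal.n_samples),
        "dtype": _SIGNAL_DTYPE,
    }
    if metadata:
        sidecar["metadata"] = metadata
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_signal(path: str | Path) -> ContinuousSignal:
    """Read an int16 + sidecar signal, validating length and encoding."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    for key in ("sampling_rate_hz", "start_time_s", "gain_uV_per_bit", "n_samples"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_file} is missing required field {key!r}")
    dtype = meta.get("dtype", _SIGNAL_DTYPE)
    if dtype != _SIGNAL_DTYPE:
        raise ValueError(f"unknown signal encoding dtype={dtype!r} (expected {_SIGNAL_DTYPE!r})")
    raw = np.fromfile(path, dtype=_SIGNAL_DTYPE)
    if raw.size != meta["n_samples"]:
        raise ValueError(
            f"binary length {raw.size} does not match sidecar n_samples {meta['n_samples']}"
        )
    samples = raw.astype(float) * meta["gain_uV_per_bit"]
    return ContinuousSignal(samples, meta["sampling_rate_hz"], meta["start_time_s"])


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    return df


def write_spikes(spikes: SpikeTrain, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"spike_time_s": np.round(spikes.spike_times, 6), "unit_id": spikes.unit_id}
    ).to_csv(path, index=False)
    return path


def read_spikes(path: str | Path) -> SpikeTrain:
    df = _read_csv(path, ["spike_time_s", "unit_id"])
    unit = str(df["unit_id"].iloc[0]) if len(df) else "unit0"
    try:
        return SpikeTrain(df["spike_time_s"].to_numpy(), unit_id=unit)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


_EVENT_COLUMNS = [
    "command_time_s",
    "delivery_time_s",
    "pulse_width_ms",
    "target_phase_rad",
    "predicted_phase_rad",
    "true_phase_rad",
]


def write_events(events: list[StimulationEvent], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "command_time_s": np.round([e.command_time for e in events], 6),
            "delivery_time_s": np.round([e.delivery_time for e in events], 6),
            "pulse_width_ms": [e.pulse_width_ms for e in events],
            "target_phase_rad": np.round([e.target_phase for e in events], 6),
            "predicted_phase_rad": np.round([e.predicted_phase_at_delivery for e in events], 6),
            "true_phase_rad": np.round([e.true_phase_at_delivery for e in events], 6),
        }
    ).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[StimulationEvent]:
    df = _read_csv(path, _EVENT_COLUMNS)
    return [
        StimulationEvent(
            command_time=row.command_time_s,
            delivery_time=row.delivery_time_s,
            pulse_width_ms=row.pulse_width_ms,
            target_phase=row.target_phase_rad,
            predicted_phase_at_delivery=row.predicted_phase_rad,
            true_phase_at_delivery=row.true_phase_rad,
        )
        for row in df.itertuples()
    ]


def write_trajectory(traj: HeadTrajectory, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": np.round(traj.timestamps, 6),
            "x_mm": traj.positions[:, 0],
            "y_mm": traj.positions[:, 1],
            "z_mm": traj.positions[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_trajectory(path: str | Path) -> HeadTrajectory:
    df = _read_csv(path, ["time_s", "x_mm", "y_mm", "z_mm"])
    try:
        return HeadTrajectory(
            timestamps=df["time_s"].to_numpy(),
            positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "start_s": [e.start for e in epochs],
            "end_s": [e.end for e in epochs],
            "condition": [e.condition for e in epochs],
        }
    ).to_csv(path, index=False)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    df = _read_csv(path, ["start_s", "end_s", "condition"])
    try:
        return EpochSet([Epoch(r.start_s, r.end_s, r.condition) for r in df.itertuples()])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
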