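"""End-to-end orchestration: simulate sessions, run the closed loop per
condition epoch, and aggregate the analytics into one JSON-able report.

A session is ``epoch_conditions`` consecutive epochs (default no_stim,
peak, trough; 30 s each). The closed loop runs independently inside each
stimulated epoch with the target phase implied by its condition (peak = 0,
trough = pi, random = Bernoulli control). Sessions get consecutive derived
seeds so a multi-session run is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .circular import circ_diff, circ_mean, circ_quartiles
from .closed_loop import evaluate_phase_accuracy, run_closed_loop
from .config import RunConfig
from .synthetic import (
    SyntheticLFP,
    apply_evoked_spikes,
    generate_head_trajectory,
    generate_lfp,
    generate_phase_locked_spikes,
)
from .types import (
    ContinuousSignal,
    Epoch,
    EpochSet,
    HeadTrajectory,
    SpikeTrain,
    StimulationEvent,
)

CONDITION_TARGETS = {"peak": 0.0, "trough": float(np.pi), "random": "random"}

# fixed offsets for deriving per-purpose sub-seeds from the session seed
_LFP, _SPIKES, _TRAJ, _EVOKED, _POLICY = 0, 1, 2, 3, 4
_SEED_STRIDE = 10


@dataclass
class SessionResult:
    """Everything simulated and measured for one session."""

    signal: ContinuousSignal
    synth: SyntheticLFP
    epochs: EpochSet
    spikes: SpikeTrain
    trajectory: HeadTrajectory
    events_by_condition: dict[str, list[StimulationEvent]] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def session_epochs(cfg: RunConfig) -> EpochSet:
    eps = [
        Epoch(i * cfg.epoch_duration, (i + 1) * cfg.epoch_duration, cond)
        for i, cond in enumerate(cfg.epoch_conditions)
    ]
    return EpochSet(eps, epoch_duration=cfg.epoch_duration)


def _target_oscillator_index(cfg: RunConfig) -> int:
    centers = [o.center_frequency for o in cfg.oscillators]
    return int(np.argmin(np.abs(np.array(centers) - cfg.band.center_frequency)))


def simulate_session(cfg: RunConfig, seed: int) -> SessionResult:
    """Generate the LFP, baseline spikes, and head track for one session."""
    epochs = session_epochs(cfg)
    duration = max(cfg.session_duration, epochs.span[1])
    synth = generate_lfp(cfg.oscillators, cfg.noise, duration, cfg.sampling_rate, seed + _LFP)
    phase = synth.phase_trace(_target_oscillator_index(cfg))
    spikes = generate_phase_locked_spikes(
        phase, cfg.sampling_rate, cfg.spikes, seed + _SPIKES, start_time=synth.signal.start_time
    )
    trajectory = generate_head_trajectory(epochs, cfg.motion, seed + _TRAJ)
    return SessionResult(
        signal=synth.signal, synth=synth, epochs=epochs, spikes=spikes, trajectory=trajectory
    )


def run_session(cfg: RunConfig, sess: SessionResult, seed: int) -> SessionResult:
    """Run the closed loop in every stimulated epoch and add evoked spikes."""
    all_events: list[StimulationEvent] = []
    for ep in sess.epochs:
        if ep.condition not in CONDITION_TARGETS:
            continue
        policy = cfg.policy(CONDITION_TARGETS[ep.condition])
        chunk = sess.signal.slice(ep.start, ep.end)
        events = run_closed_loop(chunk, policy, cfg.latency, seed=seed + _POLICY)
        sess.events_by_condition[ep.condition] = events
        all_events.extend(events)
    if all_events:
        sess.spikes = apply_evoked_spikes(sess.spikes, all_events, cfg.spikes, seed + _EVOKED)
    return sess


def analyze_session(cfg: RunConfig, sess: SessionResult) -> dict:
    """Per-epoch band power, spike-field coherence, speed, phase accuracy."""
    f0 = cfg.band.center_frequency
    speed = analysis.head_speed(sess.trajectory)
    speed_t = sess.trajectory.timestamps[:-1]

    metrics: dict = {"band_power": {}, "sfc": {}, "mean_speed": {}, "accuracy": {}}
    for ep in sess.epochs:
        chunk = sess.signal.slice(ep.start, ep.end)
        psd = analysis.compute_psd(chunk, segment_s=min(4.0, chunk.duration / 2))
        metrics["band_power"][ep.condition] = analysis.band_power(psd, cfg.band.passband)
        mask = (sess.spikes.spike_times >= ep.start) & (sess.spikes.spike_times < ep.end)
        sub = SpikeTrain(sess.spikes.spike_times[mask], unit_id=sess.spikes.unit_id)
        coh = analysis.spike_field_coherence(sub, chunk, np.array([f0]), window_s=5.0)
        metrics["sfc"][ep.condition] = float(coh.coherence[0])
        smask = (speed_t >= ep.start) & (speed_t < ep.end)
        metrics["mean_speed"][ep.condition] = float(speed[smask].mean())
        events = sess.events_by_condition.get(ep.condition, [])
        if events:
            acc = evaluate_phase_accuracy(events, sess.signal, cfg.band)
            metrics["accuracy"][ep.condition] = {
                "circular_average_rad": acc.circular_average,
                "q1_rad": acc.dispersion_interval[0],
                "q3_rad": acc.dispersion_interval[1],
                "n_events": acc.n_events,
            }
    sess.metrics = metrics
    return metrics


def _aggregate(cfg: RunConfig, sessions: list[SessionResult]) -> dict:
    conditions = cfg.epoch_conditions
    report: dict = {
        "n_sessions": len(sessions),
        "band_center_hz": cfg.band.center_frequency,
        "total_latency_ms": cfg.latency.total_ms,
    }

    def collect(key: str) -> dict[str, np.ndarray]:
        return {c: np.array([s.metrics[key][c] for s in sessions]) for c in conditions}

    # pooled achieved-phase accuracy per stimulated condition
    accuracy = {}
    for cond in conditions:
        diffs = []
        for s in sessions:
            for ev in s.events_by_condition.get(cond, []):
                if np.isfinite(ev.true_phase_at_delivery):
                    diffs.append(float(circ_diff(ev.true_phase_at_delivery, ev.target_phase)))
        if diffs:
            avg = circ_mean(diffs)
            q1, q3 = circ_quartiles(diffs, center=avg)
            accuracy[cond] = {
                "circular_average_rad": round(avg, 6),
                "q1_rad": round(q1, 6),
                "q3_rad": round(q3, 6),
                "n_events": len(diffs),
            }
    report["phase_accuracy"] = accuracy

    for key, label in (("band_power", "band_power_uV2"), ("mean_speed", "head_speed_mm_s")):
        vals = collect(key)
        report[label] = {
            c: {
                "median": round(float(np.median(v)), 6),
                "q1": round(float(np.quantile(v, 0.25)), 6),
                "q3": round(float(np.quantile(v, 0.75)), 6),
            }
            for c, v in vals.items()
        }

    def contrast(values: dict[str, np.ndarray], a: str, b: str, baseline: str | None) -> dict:
        cmp = analysis.compare_epochs(values, baseline_condition=baseline, compare=(a, b))
        return {
            "compared": [a, b],
            "normalized_medians_iqr": {
                c: [round(x, 6) for x in cmp.medians_and_iqr[c]] for c in cmp.medians_and_iqr
            },
            "rank_sum_p": round(cmp.rank_sum_p, 6),
            "cohens_d": round(cmp.cohens_d, 6),
            "percent_change": round(cmp.percent_change, 6),
        }

    if {"peak", "trough", "no_stim"} <= set(conditions) and len(sessions) >= 2:
        report["velocity_contrast"] = contrast(collect("mean_speed"), "trough", "peak", "no_stim")
        report["band_power_contrast"] = contrast(collect("band_power"), "peak", "trough", "no_stim")
        sfc = collect("sfc")
        if all(np.all(np.isfinite(v)) for v in sfc.values()):
            report["sfc_contrast"] = contrast(sfc, "peak", "trough", "no_stim")
    return report


def run_pipeline(cfg: RunConfig, seed: int | None = None) -> tuple[dict, list[SessionResult]]:
    """Simulate, stimulate, and analyze ``cfg.n_sessions`` sessions."""
    base = cfg.seed if seed is None else seed
    sessions = []
    for i in range(cfg.n_sessions):
        s = simulate_session(cfg, base + i * _SEED_STRIDE)
        s = run_session(cfg, s, base + i * _SEED_STRIDE)
        analyze_session(cfg, s)
        sessions.append(s)
    return _aggregate(cfg, sessions), sessions
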