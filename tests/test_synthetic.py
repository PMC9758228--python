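"""Generators: closed forms, spectral shape, determinism, and recovery of
the parameters they were given."""

import numpy as np
import pytest
from scipy.signal import welch

from pabst.circular import circ_mean, circ_rmse, resultant_length, wrap_phase
from pabst.phase import hilbert_phase
from pabst.synthetic import (
    MotionSpec,
    NoiseSpec,
    OscillatorSpec,
    SpikeGenSpec,
    apply_evoked_spikes,
    generate_head_trajectory,
    generate_lfp,
    generate_phase_locked_spikes,
)
from pabst.types import Epoch, EpochSet, SpikeTrain, StimulationEvent


def test_noiseless_oscillator_is_exact_cosine():
    out = generate_lfp([OscillatorSpec(4.0, amplitude=1.0)], NoiseSpec(1.0, 0.0), 1.0, 1000.0, seed=0)
    t = out.signal.times()
    assert out.signal.n_samples == 1000
    np.testing.assert_allclose(out.signal.samples, np.cos(2 * np.pi * 4 * t), atol=1e-12)
    assert out.phases[0][0] == 0.0


def test_one_over_f_noise_psd_slope():
    out = generate_lfp([], NoiseSpec(exponent=1.0, scale=1.0), 10.0, 1000.0, seed=3)
    f, p = welch(out.signal.samples, fs=1000.0, nperseg=4096)
    mask = (f >= 1) & (f <= 100)
    slope = np.polyfit(np.log10(f[mask]), np.log10(p[mask]), 1)[0]
    assert -1.3 <= slope <= -0.7


@pytest.mark.parametrize("seed", [0, 7])
def test_generators_deterministic(seed):
    spec = [OscillatorSpec(4.0, frequency_jitter_sd=0.3, amplitude_jitter_sd=0.1)]
    a = generate_lfp(spec, NoiseSpec(1.0, 0.5), 5.0, 1000.0, seed=seed)
    b = generate_lfp(spec, NoiseSpec(1.0, 0.5), 5.0, 1000.0, seed=seed)
    np.testing.assert_array_equal(a.signal.samples, b.signal.samples)
    np.testing.assert_array_equal(a.phases[0], b.phases[0])

    sp = SpikeGenSpec(base_rate=5.0, locking_concentration=2.0)
    s1 = generate_phase_locked_spikes(a.phases[0], 1000.0, sp, seed=seed)
    s2 = generate_phase_locked_spikes(b.phases[0], 1000.0, sp, seed=seed)
    np.testing.assert_array_equal(s1.spike_times, s2.spike_times)

    eps = EpochSet([Epoch(0, 10, "no_stim"), Epoch(10, 20, "trough")])
    t1 = generate_head_trajectory(eps, MotionSpec(), seed=seed)
    t2 = generate_head_trajectory(eps, MotionSpec(), seed=seed)
    np.testing.assert_array_equal(t1.positions, t2.positions)


def test_lfp_input_validation():
    with pytest.raises(ValueError):
        generate_lfp([OscillatorSpec(4.0)], NoiseSpec(), -1.0, 1000.0, seed=0)
    with pytest.raises(ValueError):
        # below 4x Nyquist margin of the fastest oscillator
        generate_lfp([OscillatorSpec(100.0, max_frequency_deviation=4.0)], NoiseSpec(), 1.0, 300.0, seed=0)


def test_lfp_psd_peak_at_center_frequency():
    out = generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.2), 60.0, 1000.0, seed=5)
    f, p = welch(out.signal.samples, fs=1000.0, nperseg=8192)
    mask = f >= 1.0  # ignore the 1/f noise pile-up near DC
    peak = f[mask][np.argmax(p[mask])]
    assert abs(peak - 4.0) <= 1000.0 / 8192  # within one frequency bin


def test_jittered_oscillator_stays_inside_excursion_band():
    out = generate_lfp(
        [OscillatorSpec(4.0, frequency_jitter_sd=0.2)], NoiseSpec(1.0, 0.2), 60.0, 1000.0, seed=5
    )
    assert out.frequencies[0].min() >= 2.0 and out.frequencies[0].max() <= 6.0
    f, p = welch(out.signal.samples, fs=1000.0, nperseg=8192)
    mask = f >= 1.0
    peak = f[mask][np.argmax(p[mask])]
    assert 2.0 <= peak <= 6.0


def test_ground_truth_phase_matches_hilbert_oracle():
    out = generate_lfp(
        [OscillatorSpec(4.0, frequency_jitter_sd=0.3)], NoiseSpec(1.0, 0.0), 60.0, 1000.0, seed=2
    )
    oracle = hilbert_phase(out.signal, (2.0, 8.0))
    sl = slice(2000, -2000)  # exclude filter edges
    assert circ_rmse(wrap_phase(out.phases[0][sl]), oracle[sl]) < 0.05


def test_homogeneous_poisson_rate_at_zero_kappa():
    out = generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.0), 100.0, 1000.0, seed=0)
    spec = SpikeGenSpec(base_rate=5.0, locking_concentration=0.0)
    spikes = generate_phase_locked_spikes(out.phases[0], 1000.0, spec, seed=11)
    expected = 5.0 * 100.0
    se = np.sqrt(expected)
    assert abs(spikes.n_spikes - expected) <= 3 * se


def test_spike_phase_locking_matches_von_mises_oracle():
    """Spike phases at kappa=5 concentrate at the preferred phase, like a
    direct von Mises sample of the same size."""
    out = generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.0), 100.0, 1000.0, seed=0)
    spec = SpikeGenSpec(base_rate=10.0, locking_concentration=5.0, preferred_phase=0.0)
    spikes = generate_phase_locked_spikes(out.phases[0], 1000.0, spec, seed=12)
    assert spikes.n_spikes >= 500
    phases = wrap_phase(np.interp(spikes.spike_times, out.signal.times(), out.phases[0]))
    assert abs(circ_mean(phases)) < 0.1
    rng = np.random.default_rng(12)
    oracle = rng.vonmises(0.0, 5.0, spikes.n_spikes)
    assert resultant_length(phases) == pytest.approx(resultant_length(oracle), abs=0.05)


def test_spike_concentration_monotone_in_kappa():
    out = generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.0), 100.0, 1000.0, seed=0)
    t = out.signal.times()
    mean_r = []
    for kappa in [0.0, 1.0, 2.0, 5.0]:
        rs = []
        for seed in range(10):
            spec = SpikeGenSpec(base_rate=5.0, locking_concentration=kappa)
            spikes = generate_phase_locked_spikes(out.phases[0], 1000.0, spec, seed=seed)
            phases = wrap_phase(np.interp(spikes.spike_times, t, out.phases[0]))
            rs.append(resultant_length(phases))
        mean_r.append(np.mean(rs))
    assert np.all(np.diff(mean_r) > 0)


def test_spike_edge_cases():
    out = generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.0), 1.0, 1000.0, seed=0)
    empty = generate_phase_locked_spikes(out.phases[0], 1000.0, SpikeGenSpec(base_rate=0.0), seed=0)
    assert empty.n_spikes == 0
    with pytest.raises(ValueError):
        generate_phase_locked_spikes(np.empty(0), 1000.0, SpikeGenSpec(), seed=0)


def _events(n, spacing=0.5, start=1.0):
    return [
        StimulationEvent(
            command_time=start + i * spacing,
            delivery_time=start + i * spacing + 0.001,
            pulse_width_ms=5.0,
            target_phase=0.0,
            predicted_phase_at_delivery=0.0,
        )
        for i in range(n)
    ]


def test_evoked_spikes_certain_and_never():
    base = SpikeTrain(np.arange(0.05, 10.0, 0.1))
    events = _events(10)
    spec = SpikeGenSpec(evoked_probability=1.0, evoked_latency_ms=3.0)
    out = apply_evoked_spikes(base, events, spec, seed=0)
    assert out.n_spikes == base.n_spikes + 10
    added = np.setdiff1d(out.spike_times, base.spike_times)
    deliveries = np.array([e.delivery_time for e in events])
    assert np.all(np.min(np.abs(added[:, None] - deliveries[None, :]), axis=1) <= 0.005)

    out0 = apply_evoked_spikes(base, events, SpikeGenSpec(evoked_probability=0.0), seed=0)
    np.testing.assert_array_equal(out0.spike_times, base.spike_times)


def test_evoked_spike_count_binomial():
    base = SpikeTrain(np.array([1000.0]))
    events = _events(1000, spacing=0.1, start=0.0)
    spec = SpikeGenSpec(evoked_probability=0.5, evoked_latency_ms=3.0)
    out = apply_evoked_spikes(base, events, spec, seed=4)
    added = out.n_spikes - base.n_spikes
    se = np.sqrt(1000 * 0.5 * 0.5)
    assert abs(added - 500) <= 3 * se


def _epochset():
    return EpochSet(
        [Epoch(0, 30, "no_stim"), Epoch(30, 60, "peak"), Epoch(60, 90, "trough")]
    )


def test_trajectory_epoch_speed_scaling():
    spec = MotionSpec(
        baseline_speed=20.0,
        condition_speed_multipliers={"no_stim": 1.0, "peak": 0.93, "trough": 1.4},
    )
    traj = generate_head_trajectory(_epochset(), spec, seed=6)
    speed = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) * spec.frame_rate
    t = traj.timestamps[:-1]
    means = {
        cond: speed[(t >= lo) & (t < hi)].mean()
        for lo, hi, cond in [(0, 30, "no_stim"), (30, 60, "peak"), (60, 90, "trough")]
    }
    ratio = means["trough"] / means["peak"]
    assert ratio == pytest.approx(1.4 / 0.93, rel=0.10)

    flat = MotionSpec(condition_speed_multipliers={"no_stim": 1.0, "peak": 1.0, "trough": 1.0})
    traj = generate_head_trajectory(_epochset(), flat, seed=7)
    speed = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) * flat.frame_rate
    t = traj.timestamps[:-1]
    m = [speed[(t >= lo) & (t < lo + 30)].mean() for lo in (0, 30, 60)]
    assert max(m) / min(m) < 1.10


def test_trajectory_zero_speed_is_stationary():
    traj = generate_head_trajectory(_epochset(), MotionSpec(baseline_speed=0.0), seed=0)
    assert np.allclose(np.diff(traj.positions, axis=0), 0.0)


def test_overlapping_epochs_rejected():
    with pytest.raises(ValueError, match="overlap"):
        EpochSet([Epoch(0, 30, "no_stim"), Epoch(20, 50, "peak")])
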