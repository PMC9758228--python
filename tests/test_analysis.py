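"""Spectra, spike-field coherence, head speed, and rank-sum contrasts."""

import itertools

import numpy as np
import pytest

from pabst.analysis import (
    band_power,
    compare_epochs,
    compute_psd,
    head_speed,
    sliding_spike_field_coherence,
    spike_field_coherence,
)
from pabst.synthetic import NoiseSpec, OscillatorSpec, SpikeGenSpec, generate_lfp, generate_phase_locked_spikes
from pabst.types import ContinuousSignal, HeadTrajectory, SpikeTrain

FS = 1000.0


def _sinusoid(freq, duration, amplitude=1.0):
    t = np.arange(int(duration * FS)) / FS
    return ContinuousSignal(amplitude * np.cos(2 * np.pi * freq * t), FS)


class TestPSD:
    def test_sinusoid_peak_and_parseval(self):
        psd = compute_psd(_sinusoid(4.0, 30.0), segment_s=4.0)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(4.0, abs=0.3)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(0.5, rel=0.05)  # mean square of unit cosine

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        sigma = 2.0
        sig = ContinuousSignal(rng.normal(0, sigma, 60000), FS)
        psd = compute_psd(sig, segment_s=2.0)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(sigma**2, rel=0.10)

    def test_zero_signal_zero_spectrum(self):
        psd = compute_psd(ContinuousSignal(np.zeros(8000), FS), segment_s=2.0)
        assert np.all(psd.power == 0.0)

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(_sinusoid(4.0, 1.0), segment_s=4.0)


class TestBandPower:
    def test_band_separation(self):
        psd = compute_psd(_sinusoid(4.0, 30.0), segment_s=4.0)
        in_band = band_power(psd, (3.0, 5.0))
        out_band = band_power(psd, (15.0, 25.0))
        assert in_band == pytest.approx(0.5, rel=0.05)
        assert out_band < 0.01 * in_band

    def test_two_equal_sinusoids_symmetric(self):
        t = np.arange(int(30 * FS)) / FS
        sig = ContinuousSignal(np.cos(2 * np.pi * 4 * t) + np.cos(2 * np.pi * 20 * t), FS)
        psd = compute_psd(sig, segment_s=4.0)
        p4 = band_power(psd, (3.0, 5.0))
        p20 = band_power(psd, (19.0, 21.0))
        assert p4 == pytest.approx(p20, rel=0.05)

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(1)
        sig = ContinuousSignal(rng.standard_normal(120000), FS)
        psd = compute_psd(sig, segment_s=2.0)
        p_narrow = band_power(psd, (100.0, 150.0))
        p_wide = band_power(psd, (200.0, 300.0))
        assert p_wide / p_narrow == pytest.approx(2.0, rel=0.10)

    def test_degenerate_band_rejected(self):
        psd = compute_psd(_sinusoid(4.0, 10.0), segment_s=2.0)
        with pytest.raises(ValueError):
            band_power(psd, (5.0, 5.0))


class TestSpikeFieldCoherence:
    def test_perfect_locking_high_coherence(self):
        lfp = _sinusoid(4.0, 60.0)
        spikes = SpikeTrain(np.arange(0.25, 59.9, 0.25))  # one spike per peak
        res = spike_field_coherence(spikes, lfp, np.array([4.0]), window_s=5.0)
        assert res.coherence[0] > 0.9

    def test_independent_spikes_below_shuffle_null(self):
        out = generate_lfp(
            [OscillatorSpec(4.0, frequency_jitter_sd=0.2)], NoiseSpec(1.0, 0.3), 60.0, FS, seed=3
        )
        spec = SpikeGenSpec(base_rate=5.0, locking_concentration=0.0)
        spikes = generate_phase_locked_spikes(out.phases[0], FS, spec, seed=5)
        obs = spike_field_coherence(spikes, out.signal, np.array([4.0]), window_s=3.0).coherence[0]
        rng = np.random.default_rng(6)
        null = []
        for _ in range(50):
            shuffled = SpikeTrain(np.sort(rng.uniform(0, 60.0, spikes.n_spikes)))
            null.append(
                spike_field_coherence(shuffled, out.signal, np.array([4.0]), window_s=3.0).coherence[0]
            )
        assert obs <= np.quantile(null, 0.95)

    def test_coherence_bounded_and_undefined_flagged(self):
        lfp = _sinusoid(4.0, 20.0)
        with pytest.warns(UserWarning, match="indeterminate"):
            res = spike_field_coherence(SpikeTrain(np.empty(0)), lfp, np.array([4.0]))
        assert res.n_windows_used == 0
        assert np.all(np.isnan(res.coherence))
        # one usable window is also indeterminate (trivially 1), not a number
        sparse = SpikeTrain(np.array([1.0, 1.5, 2.0]))
        res = spike_field_coherence(sparse, lfp, np.array([4.0]), window_s=5.0)
        assert np.all(np.isnan(res.coherence))

    def test_sliding_variant_flags_empty_windows(self):
        lfp = _sinusoid(4.0, 40.0)
        spikes = SpikeTrain(np.arange(0.25, 19.9, 0.25))  # spikes only in first half
        times, values = sliding_spike_field_coherence(spikes, lfp, 4.0, window_s=10.0)
        assert times.size == 4
        assert np.all(np.isfinite(values[:2]))
        assert np.all(np.isnan(values[2:]))
        assert np.nanmin(values) >= 0 and np.nanmax(values) <= 1


class TestHeadSpeed:
    def test_stationary_and_straight_line(self):
        n = 240
        t = np.arange(n) / 120.0
        still = HeadTrajectory(t, np.zeros((n, 3)))
        assert np.allclose(head_speed(still), 0.0)
        line = HeadTrajectory(t, np.column_stack([np.arange(n) * 1.0, np.zeros(n), np.zeros(n)]))
        speed = head_speed(line)
        assert speed.size == n - 1
        assert np.allclose(speed, 120.0)

    def test_circular_path_matches_arc_length(self):
        fps, radius, rev_per_s = 120.0, 10.0, 1.0
        t = np.arange(0, 5, 1 / fps)
        pos = np.column_stack(
            [radius * np.cos(2 * np.pi * rev_per_s * t), radius * np.sin(2 * np.pi * rev_per_s * t), np.zeros(t.size)]
        )
        speed = head_speed(HeadTrajectory(t, pos), smoothing_window_frames=1)
        assert np.median(speed) == pytest.approx(2 * np.pi * radius * rev_per_s, rel=0.02)

    def test_non_uniform_timestamps_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(ValueError, match="uniform"):
            HeadTrajectory(t, np.zeros((4, 3)))


def _exact_ranksum_p(x, y):
    """Exhaustive two-sided rank-sum p: enumerate every assignment of ranks."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    mu = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mu) >= abs(obs - mu) - 1e-12)
    return extreme / len(sums)


class TestCompareEpochs:
    def test_fully_separated_groups_exact_p(self):
        values = {"trough": np.array([2.0, 2.1, 2.2, 2.3, 2.4, 2.5]),
                  "peak": np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5])}
        cmp = compare_epochs(values, compare=("trough", "peak"))
        assert cmp.rank_sum_p == pytest.approx(2 / 924, abs=1e-12)
        assert f"{cmp.rank_sum_p:.3f}" == "0.002"
        assert cmp.rank_sum_p == pytest.approx(
            _exact_ranksum_p(values["trough"], values["peak"]), abs=1e-12
        )

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        x, y = rng.normal(0.3, 1, n), rng.normal(0, 1, n)
        cmp = compare_epochs({"a": x, "b": y}, compare=("a", "b"))
        assert cmp.rank_sum_p == pytest.approx(_exact_ranksum_p(x, y), abs=1e-12)

    def test_identical_groups(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        cmp = compare_epochs({"a": v.copy(), "b": v.copy()}, compare=("a", "b"))
        assert cmp.cohens_d == 0.0
        assert cmp.rank_sum_p == pytest.approx(1.0, abs=0.01)

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(1.0, 1.0, 4000), rng.normal(0.0, 1.0, 4000)
        cmp = compare_epochs({"a": a, "b": b}, compare=("a", "b"))
        assert cmp.cohens_d == pytest.approx(1.0, abs=0.08)

    def test_normalization_identity_and_ratios(self):
        values = {
            "no_stim": np.array([10.0, 20.0, 30.0]),
            "trough": np.array([14.0, 26.0, 42.0]),
            "peak": np.array([9.0, 19.0, 27.0]),
        }
        cmp = compare_epochs(values, baseline_condition="no_stim", compare=("trough", "peak"))
        assert cmp.medians_and_iqr["no_stim"][0] == pytest.approx(1.0)
        assert cmp.per_session_values["trough"][0] == pytest.approx(1.4)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_epochs({"a": np.array([1.0]), "b": np.array([1.0, 2.0])}, compare=("a", "b"))
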