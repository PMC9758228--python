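"""Offline analytics: spectra, spike-field coherence, head speed, and
nonparametric condition contrasts.

The statistics follow the experiment's conventions: continuous measures are
summarized as medians with inter-quartile ranges, group contrasts use the
two-sided Wilcoxon rank-sum test (exact when there are no ties), and effect
sizes are pooled-SD Cohen's d.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats

from .types import (
    CoherenceResult,
    ContinuousSignal,
    EpochComparison,
    HeadTrajectory,
    SpectrumResult,
    SpikeTrain,
)

__all__ = [
    "compute_psd",
    "band_power",
    "spike_field_coherence",
    "sliding_spike_field_coherence",
    "head_speed",
    "compare_epochs",
]

SPIKE_BIN_S = 0.001  # 1 ms spike binning for coherence


def compute_psd(
    signal: ContinuousSignal, segment_s: float = 4.0, overlap_fraction: float = 0.5
) -> SpectrumResult:
    """Welch power spectral density with Hann tapering.

    ``segment_s`` sets the frequency resolution (1/segment_s Hz);
    the integral of the returned density approximates the signal variance
    (Parseval).
    """
    nperseg = int(round(segment_s * signal.sampling_rate))
    if nperseg > signal.n_samples:
        raise ValueError("segment longer than signal")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, power = sps.welch(
        signal.samples,
        fs=signal.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)),
        detrend=False,
    )
    return SpectrumResult(frequencies=freqs, power=power)


def band_power(spectrum: SpectrumResult, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over ``band`` (uV^2)."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("band must satisfy low < high")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than two frequency grid points")
    return float(np.trapezoid(spectrum.power[mask], spectrum.frequencies[mask]))


def _bin_pair(
    spikes: SpikeTrain, lfp: ContinuousSignal, bin_s: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bin spikes and resample the LFP onto a common grid."""
    n_bins = int(np.floor(lfp.duration / bin_s))
    edges = lfp.start_time + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spikes.spike_times, bins=edges)
    centers = edges[:-1] + bin_s / 2.0
    lfp_binned = np.interp(centers, lfp.times(), lfp.samples)
    return counts.astype(float), lfp_binned, 1.0 / bin_s


def spike_field_coherence(
    spikes: SpikeTrain,
    lfp: ContinuousSignal,
    frequencies: np.ndarray,
    window_s: float = 5.0,
    overlap_fraction: float = 0.0,
) -> CoherenceResult:
    """Magnitude-squared coherence between a binned spike train and the LFP.

    Spikes are binned at 1 ms and mean-subtracted per window; cross- and
    auto-spectra (Hann taper) are averaged over windows that contain at
    least one spike. Windows without spikes are excluded; with fewer than
    two usable windows the coherence is indeterminate and reported as NaN
    (a single window would be trivially 1), never silently zero.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if window_s < 2.0 / frequencies.min():
        raise ValueError("window_s must cover at least two cycles of the lowest frequency")
    if spikes.n_spikes == 0:
        warnings.warn("empty spike train: coherence is indeterminate everywhere")
        return CoherenceResult(frequencies, np.full(frequencies.shape, np.nan), 0)

    x, y, fs_bin = _bin_pair(spikes, lfp, SPIKE_BIN_S)
    nper = int(round(window_s * fs_bin))
    step = max(1, int(round(nper * (1 - overlap_fraction))))
    taper = sps.windows.hann(nper)

    sxx = syy = sxy = 0.0
    n_used = 0
    for start in range(0, x.size - nper + 1, step):
        xs = x[start : start + nper]
        if xs.sum() == 0:
            continue
        ys = y[start : start + nper]
        fx = np.fft.rfft((xs - xs.mean()) * taper)
        fy = np.fft.rfft((ys - ys.mean()) * taper)
        sxx = sxx + np.abs(fx) ** 2
        syy = syy + np.abs(fy) ** 2
        sxy = sxy + fx * np.conj(fy)
        n_used += 1

    if n_used < 2:
        return CoherenceResult(frequencies, np.full(frequencies.shape, np.nan), n_used)
    grid = np.fft.rfftfreq(nper, d=1.0 / fs_bin)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    out = np.interp(frequencies, grid, coh)
    return CoherenceResult(frequencies, np.clip(out, 0.0, 1.0), n_used)


def sliding_spike_field_coherence(
    spikes: SpikeTrain,
    lfp: ContinuousSignal,
    frequency: float,
    window_s: float = 10.0,
    subwindow_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved coherence at one frequency.

    Each window is scored with :func:`spike_field_coherence` over
    sub-windows (default window_s / 4); windows whose coherence is
    indeterminate (too few spike-containing sub-windows) are NaN, matching
    real recordings where sparse firing makes the value indeterminate.

    Returns ``(window_center_times, coherence_values)``.
    """
    if subwindow_s is None:
        subwindow_s = window_s / 4.0
    t0, t1 = lfp.start_time, lfp.end_time
    starts = np.arange(t0, t1 - window_s + 1e-9, window_s)
    times = starts + window_s / 2.0
    values = np.full(starts.size, np.nan)
    for i, s in enumerate(starts):
        chunk = lfp.slice(s, s + window_s)
        mask = (spikes.spike_times >= s) & (spikes.spike_times < s + window_s)
        sub = SpikeTrain(spikes.spike_times[mask], unit_id=spikes.unit_id)
        if sub.n_spikes == 0:
            continue
        res = spike_field_coherence(sub, chunk, np.array([frequency]), window_s=subwindow_s)
        values[i] = res.coherence[0]
    return times, values


def head_speed(traj: HeadTrajectory, smoothing_window_frames: int = 12) -> np.ndarray:
    """Head speed (mm/s) from frame-to-frame displacement.

    Output has ``n_frames - 1`` samples; a centered moving average of
    ``smoothing_window_frames`` (default 12 frames = 100 ms at 120 frames/s)
    suppresses tracking jitter. Edges use the partial window.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    disp = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    speed = disp * traj.frame_rate
    k = int(smoothing_window_frames)
    if k > 1:
        kernel = np.ones(k)
        norm = np.convolve(np.ones_like(speed), kernel, mode="same")
        speed = np.convolve(speed, kernel, mode="same") / norm
    return speed


def compare_epochs(
    values_by_condition: dict[str, np.ndarray],
    baseline_condition: str | None = None,
    compare: tuple[str, str] | None = None,
) -> EpochComparison:
    """Contrast per-session values across conditions.

    When ``baseline_condition`` is given, each session's values are first
    divided by that session's baseline value (sessions are aligned by
    index), yielding ratios near 1. The two ``compare`` conditions (default:
    the first two non-baseline conditions) are tested with the two-sided
    Wilcoxon rank-sum test — exact when there are no ties, normal
    approximation with midranks otherwise — plus pooled-SD Cohen's d and
    the percent change of medians.
    """
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_condition.items()}
    for c, v in values.items():
        if v.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 sessions")
    if baseline_condition is not None:
        base = values[baseline_condition]
        if np.any(base == 0):
            raise ValueError("baseline values must be nonzero for normalization")
        n = base.size
        for c, v in values.items():
            if v.size != n:
                raise ValueError("normalization requires aligned sessions per condition")
        values = {c: v / base for c, v in values.items()}

    summaries = {
        c: (
            float(np.median(v)),
            float(np.quantile(v, 0.25)),
            float(np.quantile(v, 0.75)),
        )
        for c, v in values.items()
    }
    if compare is None:
        non_base = [c for c in values if c != baseline_condition]
        if len(non_base) < 2:
            raise ValueError("need two conditions to compare")
        compare = (non_base[0], non_base[1])
    a, b = values[compare[0]], values[compare[1]]

    # exact null enumeration is only tractable for small groups; with ties
    # (midranks) or large n, fall back to the normal approximation
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if not has_ties and a.size + b.size <= 60 else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)

    pooled_sd = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    d = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    med_a, med_b = np.median(a), np.median(b)
    pct = float((med_a - med_b) / med_b * 100.0) if med_b != 0 else float("nan")

    return EpochComparison(
        per_session_values=values,
        medians_and_iqr=summaries,
        compared_conditions=compare,
        rank_sum_p=min(p, 1.0),
        cohens_d=d,
        percent_change=pct,
    )
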