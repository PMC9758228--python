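"""Wavelet phase estimation and forward phase prediction.

A complex Morlet kernel (Gaussian-windowed complex exponential, temporal SD
n_cycles / (2*pi*f), unit L2 norm, admissibility-corrected so its real part
has zero mean) is convolved with the signal; the coefficient's argument is
the instantaneous phase and its magnitude the band amplitude.

Causal use: the newest time point a kernel of half-length L/2 can cover in
a buffer ending at time T is T - L/2 — that group delay ("estimation lag")
is separate from, and added to, the hardware latency budget when predicting
forward.

Instantaneous frequency is the least-squares slope of the unwrapped
coefficient phase over the most recent 25 ms, clamped to the band's
passband. Forward prediction is linear: phase + 2*pi*frequency*horizon.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, oaconvolve

from .circular import circ_diff, wrap_phase
from .types import BandSpec, ContinuousSignal, PhaseEstimate

__all__ = [
    "morlet_kernel",
    "wavelet_transform",
    "estimate_phase",
    "predict_phase",
    "hilbert_phase",
    "frequency_to_period_ms",
    "wrap_phase",
    "circ_diff",
]

FREQ_FIT_WINDOW_S = 0.025  # span of coefficients used for the frequency fit

_AMP_EPS = 1e-12


def morlet_kernel(band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Complex Morlet kernel for ``band`` at ``sampling_rate``.

    Length is ``n_cycles / center_frequency`` seconds (odd sample count);
    the temporal SD is n_cycles / (2*pi*center_frequency), so the Gaussian
    envelope is truncated at ~3.14 SDs. The oscillatory part has the DC
    term subtracted (admissibility) and the kernel has unit L2 norm.
    """
    if sampling_rate < 4 * band.center_frequency:
        raise ValueError("sampling_rate must be >= 4x the band center frequency")
    f = band.center_frequency
    sigma_t = band.n_cycles / (2 * np.pi * f)
    half_n = int(round(0.5 * band.n_cycles / f * sampling_rate))
    t = np.arange(-half_n, half_n + 1) / sampling_rate
    envelope = np.exp(-(t**2) / (2 * sigma_t**2))
    carrier = np.exp(1j * 2 * np.pi * f * t)
    # exact discrete admissibility: subtract the carrier's leakage onto the
    # envelope so the kernel sums to zero (no DC response)
    dc = np.sum(envelope * carrier) / np.sum(envelope)
    kernel = envelope * (carrier - dc)
    kernel /= np.linalg.norm(kernel)
    return kernel


def kernel_half_length(band: BandSpec, sampling_rate: float) -> int:
    """Samples from kernel center to either edge."""
    return int(round(0.5 * band.n_cycles / band.center_frequency * sampling_rate))


def wavelet_transform(signal: ContinuousSignal, band: BandSpec) -> np.ndarray:
    """Complex wavelet coefficients at every sample (center-aligned).

    Coefficient k depends only on samples within +/- half a kernel of k, so
    coefficients with ``k <= newest_available - half_kernel`` are causal.
    Edge coefficients (within half a kernel of either end) use zero padding.
    """
    kernel = morlet_kernel(band, signal.sampling_rate)
    # conjugate so the coefficient argument equals the signal phase
    return oaconvolve(signal.samples, np.conj(kernel[::-1]), mode="same")


def _fit_frequency(
    coeffs: np.ndarray, center_idx: np.ndarray, sampling_rate: float, band: BandSpec
) -> np.ndarray:
    """Least-squares slope of unwrapped coefficient phase ending at center_idx."""
    k = max(2, int(round(FREQ_FIT_WINDOW_S * sampling_rate)))
    offsets = np.arange(-k + 1, 1)
    idx = np.atleast_1d(center_idx)[:, None] + offsets[None, :]
    ph = np.unwrap(np.angle(coeffs[idx]), axis=1)
    x = offsets / sampling_rate
    w = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
    slope = ph @ w  # rad/s
    freq = slope / (2 * np.pi)
    return np.clip(freq, band.passband[0], band.passband[1])


def estimate_phase(window: ContinuousSignal, band: BandSpec) -> PhaseEstimate:
    """Estimate phase/frequency/amplitude at the newest coverable time point
    of a buffered window (its end minus half a kernel).

    An all-zero (or numerically negligible) band amplitude yields an
    estimate with ``phase_defined=False`` and amplitude 0.
    """
    fs = window.sampling_rate
    half = kernel_half_length(band, fs)
    kfit = max(2, int(round(FREQ_FIT_WINDOW_S * fs)))
    needed = 2 * half + 1 + (kfit - 1)
    if window.n_samples < needed:
        raise ValueError(
            f"window of {window.n_samples} samples is shorter than the "
            f"kernel + frequency-fit span ({needed} samples)"
        )
    coeffs = wavelet_transform(window, band)
    center = window.n_samples - 1 - half
    t = window.start_time + center / fs
    amp = float(np.abs(coeffs[center]))
    if amp < _AMP_EPS:
        return PhaseEstimate(
            time=t, phase=0.0, frequency=band.center_frequency, amplitude=0.0, phase_defined=False
        )
    freq = float(_fit_frequency(coeffs, np.array([center]), fs, band)[0])
    phase = float(np.angle(coeffs[center]))
    return PhaseEstimate(time=t, phase=phase, frequency=freq, amplitude=amp)


def predict_phase(estimate: PhaseEstimate, horizon: float) -> float:
    """Linearly extrapolate phase ``horizon`` seconds ahead, wrapped."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if not estimate.phase_defined:
        raise ValueError("cannot predict from an undefined phase estimate")
    return wrap_phase(estimate.phase + 2 * np.pi * estimate.frequency * horizon)


def hilbert_phase(signal: ContinuousSignal, passband: tuple[float, float]) -> np.ndarray:
    """Acausal ground-truth phase: zero-phase band-pass then analytic signal.

    This is the offline oracle against which achieved stimulation phase is
    scored; it is acausal (filtfilt) and unusable in real time.
    """
    nyq = signal.sampling_rate / 2.0
    lo, hi = passband
    if not 0 < lo < hi < nyq:
        raise ValueError("passband must lie strictly inside (0, Nyquist)")
    b, a = butter(4, [lo / nyq, hi / nyq], btype="bandpass")
    filtered = filtfilt(b, a, signal.samples)
    return np.angle(hilbert(filtered))


def frequency_to_period_ms(frequency: float) -> float:
    """Oscillation period in milliseconds (50 ms at 20 Hz)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 / frequency
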