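"""Directional statistics for phase angles.

All angles are radians under the cosine convention (0 = oscillation peak,
pi = trough) and are wrapped to the half-open interval (-pi, pi].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_phase",
    "circ_diff",
    "circ_mean",
    "resultant_length",
    "circ_rmse",
    "circ_quartiles",
    "rayleigh_test",
]

_TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angle(s) into (-pi, pi].

    ``wrap_phase(2*pi) == 0`` and ``wrap_phase(-pi) == pi``; idempotent.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_phase requires finite input")
    # map to [-pi, pi) then move the closed endpoint to +pi
    y = np.mod(x + np.pi, _TWO_PI) - np.pi
    y = np.where(y == -np.pi, np.pi, y)
    if y.ndim == 0:
        return float(y)
    return y


def circ_diff(a, b):
    """Signed shortest-arc difference ``a - b``, wrapped into (-pi, pi]."""
    return wrap_phase(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def _resultant(angles: np.ndarray) -> complex:
    return np.exp(1j * np.asarray(angles, dtype=float)).mean()

def circ_mean(angles) -> float:
    """Circular mean: argument of the mean resultant vector."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular mean of an empty set is undefined")
    return wrap_phase(float(np.angle(_resultant(angles))))


def resultant_length(angles) -> float:
    """Mean resultant length R-bar in [0, 1]; 1 = perfectly concentrated."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("resultant length of an empty set is undefined")
    return float(np.abs(_resultant(angles)))


def circ_rmse(a, b) -> float:
    """Root-mean-square of the wrapped difference between two angle series."""
    d = circ_diff(a, b)
    return float(np.sqrt(np.mean(np.square(d))))


def circ_quartiles(angles, center: float | None = None) -> tuple[float, float]:
    """(Q1, Q3) of angles, taken as linear quartiles of deviations around the
    circular mean (or a supplied center) and mapped back to the circle.

    Meaningful for unimodal samples concentrated within less than a full turn.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("quartiles of an empty set are undefined")
    if center is None:
        center = circ_mean(angles)
    dev = circ_diff(angles, center)
    q1, q3 = np.quantile(dev, [0.25, 0.75])
    return wrap_phase(center + q1), wrap_phase(center + q3)


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` where ``z = n * Rbar**2`` and ``p`` uses Zar's
    finite-sample correction. Small p rejects uniformity (i.e. the sample is
    phase-concentrated).
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("Rayleigh test of an empty set is undefined")
    rbar = resultant_length(angles)
    big_r = n * rbar
    z = big_r**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))
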