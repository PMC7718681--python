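"""Band-pass filtering and kinematic derivations applied before feature extraction.

Two Butterworth bands are used: a 2nd-order 0.3-20 Hz band on every raw IMU
channel (drift removal below, out-of-movement-band noise above), and a
6th-order 2-5 Hz band isolating the oscillatory component before spectral
peak features.  Both are applied zero-phase (forward-backward), so event
timing is preserved across channels at the cost of doubling the effective
order.  Angular acceleration is a central finite difference of angular rate;
angle is a cumulative trapezoid of angular rate with the mean removed to
suppress integration drift.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, signal


def _butter_sos(low: float, high: float, sample_rate: float, order: int):
    nyq = sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={nyq}) Hz")
    return signal.butter(order, [low, high], btype="bandpass",
                         fs=sample_rate, output="sos")


def bandpass_imu(x: np.ndarray, sample_rate: float,
                 low: float = 0.3, high: float = 20.0,
                 order: int = 2) -> np.ndarray:
    """Zero-phase 0.3-20 Hz band-pass of one IMU channel."""
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * order:
        raise ValueError("series too short for the filter order")
    sos = _butter_sos(low, high, sample_rate, order)
    return signal.sosfiltfilt(sos, x)


def bandpass_spectral(x: np.ndarray, sample_rate: float,
                      low: float = 2.0, high: float = 5.0,
                      order: int = 6) -> np.ndarray:
    """Zero-phase 2-5 Hz band-pass used before resonant-frequency features."""
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * order:
        raise ValueError("series too short for the filter order")
    sos = _butter_sos(low, high, sample_rate, order)
    return signal.sosfiltfilt(sos, x)


def angular_acceleration(gyro: np.ndarray, sample_rate: float) -> np.ndarray:
    """Angular acceleration from one angular-rate axis.

    Central differences in the interior, one-sided at the ends, so the output
    has the same length as the input.
    """
    gyro = np.asarray(gyro, dtype=float)
    if gyro.size < 3:
        raise ValueError("need at least 3 samples")
    return np.gradient(gyro, 1.0 / sample_rate)


def angle_from_gyro(gyro: np.ndarray, sample_rate: float) -> np.ndarray:
    """Angle from one angular-rate axis: cumulative trapezoid, mean removed.

    The input is assumed already band-passed; mean removal suppresses the
    residual linear drift of the integral.
    """
    gyro = np.asarray(gyro, dtype=float)
    ang = integrate.cumulative_trapezoid(gyro, dx=1.0 / sample_rate, initial=0.0)
    return ang - ang.mean()


def frequency_response(sample_rate: float, low: float, high: float,
                       order: int, freqs: np.ndarray) -> np.ndarray:
    """|H(f)|^2-effective gain of the zero-phase filter at the given frequencies.

    Forward-backward application squares the magnitude response; this is the
    analytic oracle used to verify pass-band/stop-band behaviour.
    """
    sos = _butter_sos(low, high, sample_rate, order)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float),
                           fs=sample_rate)
    return np.abs(h) ** 2
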