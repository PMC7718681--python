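"""IMU-based features: tapping rhythm (FTT) and spectral oscillation (FNT/DDKT).

FTT yields the coefficient of variation of inter-tap intervals (CITI) plus
fuzzy entropy of selected channels; FNT and DDKT yield the resonant
frequency (RF, dominant spectral peak) and its magnitude (MR) of oscillatory
channels after 2-5 Hz band-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .core_io import AnalysisConfig, ImuRecording
from .preprocess import (angle_from_gyro, angular_acceleration, bandpass_imu,
                         bandpass_spectral)


# --------------------------------------------------------------------------
# finger tapping
# --------------------------------------------------------------------------

@dataclass
class TapSeries:
    """Detected tap contacts and their inter-tap intervals (ITI), seconds."""

    tap_times: np.ndarray

    def __post_init__(self) -> None:
        self.tap_times = np.asarray(self.tap_times, dtype=float)
        if np.any(np.diff(self.tap_times) <= 0):
            raise ValueError("tap times must be strictly increasing")

    @property
    def iti(self) -> np.ndarray:
        return np.diff(self.tap_times)


def detect_taps(accel_z: np.ndarray, sample_rate: float,
                mad_factor: float = 3.0,
                min_separation_s: float = 0.150) -> TapSeries:
    """Tap contacts as peaks of |accel Z| above ``mad_factor`` times the
    median absolute deviation, separated by at least ``min_separation_s``.
    """
    x = np.abs(np.asarray(accel_z, dtype=float))
    mad = np.median(np.abs(x - np.median(x)))
    threshold = mad_factor * mad
    peaks, _ = sp_signal.find_peaks(
        x, height=threshold,
        distance=max(1, int(round(min_separation_s * sample_rate))))
    if peaks.size < 4:
        raise ValueError(
            f"insufficient taps: found {peaks.size}, need at least 4")
    return TapSeries(tap_times=peaks / sample_rate)


def citi(taps: TapSeries) -> float:
    """Coefficient of variation of the inter-tap intervals (sample SD / mean)."""
    iti = taps.iti
    if iti.size < 3:
        raise ValueError("need at least 4 taps (3 intervals) for CITI")
    return float(np.std(iti, ddof=1) / np.mean(iti))


# --------------------------------------------------------------------------
# fuzzy entropy
# --------------------------------------------------------------------------

def _phi(y: np.ndarray, m: int, r: float) -> float:
    """Mean pairwise similarity of mean-centred length-m templates.

    Templates X_t = {x_t ... x_{t+m-1}} for t = 1..N-m, each centred on its
    own mean; similarity exp(-(d/r)^2) with d the Chebyshev distance;
    self-matches excluded.
    """
    n = y.size - m  # number of templates at dimension m
    idx = np.arange(m)[None, :] + np.arange(n)[:, None]
    templates = y[idx]
    templates = templates - templates.mean(axis=1, keepdims=True)
    # Chebyshev distance matrix over template pairs
    d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    sim = np.exp(-((d / r) ** 2))
    np.fill_diagonal(sim, 0.0)
    return float(sim.sum() / (n * (n - 1)))


def fuzzy_entropy(y: np.ndarray, m: int = 3, r: float | None = None) -> float:
    """Fuzzy entropy FuEn = ln phi^m - ln phi^{m+1} in nats.

    Quantifies the information lost when the embedding dimension grows by
    one: irregular series keep losing predictability (high FuEn), while
    stereotyped, low-complexity movement does not.  Defaults m = 3,
    r = 0.2 * std(y).
    """
    y = np.asarray(y, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(y))
    if r <= 0:
        raise ValueError("radius r must be positive (constant series?)")
    if y.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples")
    return float(np.log(_phi(y, m, r)) - np.log(_phi(y, m + 1, r)))


# --------------------------------------------------------------------------
# resonant frequency and magnitude
# --------------------------------------------------------------------------

@dataclass
class SpectralFeature:
    rf: float            # Hz, dominant spectral peak
    mr: float            # peak magnitude, input units (amplitude scale)
    signal_label: str = ""


def rf_mr(x: np.ndarray, sample_rate: float,
          signal_label: str = "") -> SpectralFeature:
    """Dominant spectral peak location (RF) and amplitude (MR) of a signal.

    Hann-windowed FFT zero-padded to the next power of two for stable peak
    location; the single-sided spectrum is scaled so a pure tone of amplitude
    A reports MR = A.  The DC bin is excluded, constraining RF to
    (0, Nyquist).
    """
    x = np.asarray(x, dtype=float)
    if np.allclose(x, 0):
        raise ValueError("all-zero signal has no spectral peak")
    n = x.size
    window = np.hanning(n)
    nfft = 1 << max(8, int(np.ceil(np.log2(n))))
    spec = np.abs(np.fft.rfft(x * window, n=nfft))
    # amplitude normalisation: tone of amplitude A -> 2*|X|/sum(window) = A
    spec *= 2.0 / window.sum()
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    peak = 1 + int(np.argmax(spec[1:]))  # skip DC
    return SpectralFeature(rf=float(freqs[peak]), mr=float(spec[peak]),
                           signal_label=signal_label)


# --------------------------------------------------------------------------
# per-recording feature maps
# --------------------------------------------------------------------------

def _filtered_channels(rec: ImuRecording, cfg: AnalysisConfig
                       ) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.imu_band
    acc = np.column_stack([
        bandpass_imu(rec.accel[:, i], rec.sample_rate, lo, hi, cfg.imu_order)
        for i in range(3)])
    gyr = np.column_stack([
        bandpass_imu(rec.gyro[:, i], rec.sample_rate, lo, hi, cfg.imu_order)
        for i in range(3)])
    return acc, gyr


def _spectral(x: np.ndarray, fs: float, cfg: AnalysisConfig,
              label: str) -> SpectralFeature:
    lo, hi = cfg.spectral_band
    return rf_mr(bandpass_spectral(x, fs, lo, hi, cfg.spectral_order), fs,
                 signal_label=label)


def extract_imu_features(rec: ImuRecording,
                         config: AnalysisConfig | None = None
                         ) -> dict[str, float]:
    """All catalog features of one IMU recording, keyed by catalog name.

    FTT: CITI from tap detection on accel Z plus fuzzy entropy of accel X,
    accel Z and gyro X (4 features).  FNT: RF/MR of angular acceleration on
    all axes, RF/MR of linear acceleration X, RF only on Y and Z (10).
    DDKT: RF/MR of the angle on X and Z, the acceleration on X and Z, and
    the angular acceleration on Y (10).  Channels are 0.3-20 Hz filtered
    first; spectral features apply the 2-5 Hz band on top.
    """
    cfg = config or AnalysisConfig()
    fs, hand = rec.sample_rate, rec.hand
    acc, gyr = _filtered_channels(rec, cfg)
    out: dict[str, float] = {}

    if rec.test == "FTT":
        taps = detect_taps(acc[:, 2], fs, cfg.tap_mad_factor,
                           cfg.tap_min_separation_s)
        out[f"CITI_FTT_Tap_{hand}"] = citi(taps)
        out[f"FuEn_FTT_AcX_{hand}"] = fuzzy_entropy(
            acc[:, 0], cfg.fuzzy_m, cfg.fuzzy_r_factor * acc[:, 0].std())
        out[f"FuEn_FTT_AcZ_{hand}"] = fuzzy_entropy(
            acc[:, 2], cfg.fuzzy_m, cfg.fuzzy_r_factor * acc[:, 2].std())
        out[f"FuEn_FTT_GyX_{hand}"] = fuzzy_entropy(
            gyr[:, 0], cfg.fuzzy_m, cfg.fuzzy_r_factor * gyr[:, 0].std())
        return out

    if rec.test == "FNT":
        for ax, name in ((0, "X"), (1, "Y"), (2, "Z")):
            sf = _spectral(angular_acceleration(gyr[:, ax], fs), fs, cfg,
                           f"AAc{name}")
            out[f"RF_FNT_AAc{name}_{hand}"] = sf.rf
            out[f"MR_FNT_AAc{name}_{hand}"] = sf.mr
        sf = _spectral(acc[:, 0], fs, cfg, "AcX")
        out[f"RF_FNT_AcX_{hand}"] = sf.rf
        out[f"MR_FNT_AcX_{hand}"] = sf.mr
        out[f"RF_FNT_AcY_{hand}"] = _spectral(acc[:, 1], fs, cfg, "AcY").rf
        out[f"RF_FNT_AcZ_{hand}"] = _spectral(acc[:, 2], fs, cfg, "AcZ").rf
        return out

    if rec.test == "DDKT":
        for ax, name in ((0, "X"), (2, "Z")):
            sf = _spectral(angle_from_gyro(gyr[:, ax], fs), fs, cfg,
                           f"Ang{name}")
            out[f"RF_DDKT_Ang{name}_{hand}"] = sf.rf
            out[f"MR_DDKT_Ang{name}_{hand}"] = sf.mr
            sf = _spectral(acc[:, ax], fs, cfg, f"Ac{name}")
            out[f"RF_DDKT_Ac{name}_{hand}"] = sf.rf
            out[f"MR_DDKT_Ac{name}_{hand}"] = sf.mr
        sf = _spectral(angular_acceleration(gyr[:, 1], fs), fs, cfg, "AAcY")
        out[f"RF_DDKT_AAcY_{hand}"] = sf.rf
        out[f"MR_DDKT_AAcY_{hand}"] = sf.mr
        return out

    raise ValueError(f"not an IMU test: {rec.test}")
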