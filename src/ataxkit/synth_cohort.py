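"""Synthetic cohort generator: graded-severity recordings for every test.

No public recording of the clinical cohort exists, so this module emulates
the four tests well enough for every pipeline stage to run and be tested:

* FCT  - target jumps on a 1920x1080 px field; the marker responds after a
         reaction delay with a minimum-jerk reach, overshoots in proportion
         to severity, and carries 2-5 Hz tremor.
* FTT  - ~15 s of tapping: a vertical oscillation with an impact spike at
         each contact; inter-tap intervals drawn with a severity-graded
         coefficient of variation; broadband movement texture that *shrinks*
         with severity (complexity loss).
* FNT/DDKT - 2-5 Hz oscillation on the primary axis whose amplitude shrinks
         with severity while secondary-axis leakage grows.

Severity s in [0, 3] drives every knob monotonically; s = 0 reproduces the
control distribution.  The SARA upper-limb sum is a linear map of s plus
rounding noise.  All Table-4-style group differences therefore have a known
direction: KiDe down, ReTi up, DTWEr up, AcAlt up, FuEn down, CITI up,
primary-axis MR down with increasing severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core_io import (FCT_N_TARGETS, FCT_SAMPLE_RATE, IMU_SAMPLE_RATE,
                      FctTrial, ImuRecording, Recording, RecordingKey,
                      SubjectRecord, write_cohort)
from .preprocess import bandpass_spectral


@dataclass
class GeneratorConfig:
    """Cohort composition and severity-to-signal effect knobs.

    Each ``*_base``/``*_slope`` pair defines a knob value base + slope*s at
    severity s; every slope's sign fixes the direction the corresponding
    extracted feature moves with severity.  Defaults are calibrated so a
    control cohort lands near a ~750 ms reaction time and a severe one near
    ~1100 ms, with tapping at ~2.5 Hz and oscillatory movement inside the
    2-5 Hz band.
    """

    n_subjects: int = 55
    ataxic_fraction: float = 41 / 55
    severity_range: tuple[float, float] = (0.5, 3.0)
    seed: int = 0

    # finger chase
    screen_px: tuple[int, int] = (1920, 1080)
    target_radius_px: float = 15.0
    event_interval_s: float = 2.0
    jump_distance_px: float = 420.0
    reach_duration_s: float = 0.5
    reaction_delay_base_ms: float = 750.0
    reaction_delay_slope_ms: float = 140.0
    overshoot_base: float = 0.02
    overshoot_slope: float = 0.06
    tremor_base_px: float = 1.0
    tremor_slope_px: float = 6.0
    marker_noise_px: float = 0.0

    # finger tapping
    ftt_duration_s: float = 15.0
    mean_iti_s: float = 0.40
    iti_cv_base: float = 0.05
    iti_cv_slope: float = 0.08
    tap_impact_amp: float = 6.0
    tap_impact_width_s: float = 0.025
    tap_osc_amp: float = 0.15
    complexity_base: float = 1.0
    complexity_slope: float = -0.25      # texture amplitude shrinks with s
    complexity_floor: float = 0.20

    # oscillatory tests (FNT / DDKT)
    osc_duration_s: float = 15.0
    primary_osc_freq_base: float = 3.5   # Hz, stays inside the 2-5 Hz band
    primary_osc_freq_slope: float = -0.3
    primary_osc_amp_base: float = 1.5
    primary_osc_amp_slope: float = -0.35
    secondary_leak_base: float = 0.10
    secondary_leak_slope: float = 0.30
    ddkt_nuisance_sd: float = 0.5    # idiosyncratic DDKT subject variability

    imu_noise_sd: float = 0.05

    # severity knobs -------------------------------------------------------
    def reaction_delay_ms(self, s: float) -> float:
        return self.reaction_delay_base_ms + self.reaction_delay_slope_ms * s

    def overshoot_gain(self, s: float) -> float:
        return self.overshoot_base + self.overshoot_slope * s

    def tremor_amp(self, s: float) -> float:
        return self.tremor_base_px + self.tremor_slope_px * s

    def iti_cv(self, s: float) -> float:
        return self.iti_cv_base + self.iti_cv_slope * s

    def complexity(self, s: float) -> float:
        return max(self.complexity_floor,
                   self.complexity_base + self.complexity_slope * s)

    def primary_osc_freq(self, s: float) -> float:
        return self.primary_osc_freq_base + self.primary_osc_freq_slope * s

    def primary_osc_amp(self, s: float) -> float:
        return max(0.2, self.primary_osc_amp_base
                   + self.primary_osc_amp_slope * s)

    def secondary_leak(self, s: float) -> float:
        return self.secondary_leak_base + self.secondary_leak_slope * s

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in raw:
            if not hasattr(cls(), key):
                raise KeyError(f"unknown generator key {key!r}")
            if isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def min_jerk(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    """Minimum-jerk trajectory from p0 to p1 in n samples (endpoints included)."""
    tau = np.linspace(0.0, 1.0, n)[:, None]
    shape = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    return p0[None, :] + (np.atleast_1d(p1) - p0)[None, :] * shape


def _narrowband(n: int, fs: float, rng: np.random.Generator,
                low: float = 2.0, high: float = 5.0) -> np.ndarray:
    """Unit-RMS 2-5 Hz noise: band-passed white noise (tremor-like, not a tone)."""
    x = bandpass_spectral(rng.standard_normal(n), fs, low, high, order=4)
    rms = np.sqrt(np.mean(x ** 2))
    return x / (rms + 1e-12)


# --------------------------------------------------------------------------
# per-test simulators
# --------------------------------------------------------------------------

def simulate_fct(cfg: GeneratorConfig, s: float, hand: str,
                 rng: np.random.Generator) -> FctTrial:
    fs = FCT_SAMPLE_RATE
    n_ev = FCT_N_TARGETS
    interval = int(round(cfg.event_interval_s * fs))
    T = n_ev * interval + interval
    w, h = cfg.screen_px
    margin = 120.0
    # target positions: fixed-length jumps in near-diagonal directions,
    # kept inside a central disc so per-axis task difficulty is uniform and
    # the target sequence does not drift across the screen (drift would
    # dominate the trial-mean-removed trajectories and mask severity)
    centre = np.array([w / 2.0, h / 2.0])
    r_max = cfg.jump_distance_px + 15.0  # disc must admit a jump from centre
    pos = [centre.copy()]
    while len(pos) < n_ev:
        ang = (rng.choice([1, 3, 5, 7]) * np.pi / 4
               + rng.uniform(-np.pi / 9, np.pi / 9))
        cand = pos[-1] + cfg.jump_distance_px * np.array([np.cos(ang),
                                                          np.sin(ang)])
        if np.linalg.norm(cand - centre) <= r_max:
            pos.append(cand)
    onsets = [k * interval for k in range(n_ev)]
    events = [(o, float(p[0]), float(p[1])) for o, p in zip(onsets, pos)]

    delay_s = cfg.reaction_delay_ms(s) / 1000.0 - cfg.reach_duration_s / 2.0
    delay = max(1, int(round(delay_s * fs)))
    move = max(2, int(round(cfg.reach_duration_s * fs)))
    settle = max(2, int(round(0.3 * fs)))

    marker = np.zeros((T, 2))
    cur = pos[0].copy()
    marker[:] = cur
    for k in range(1, n_ev):
        start = onsets[k] + delay
        tgt = pos[k]
        direction = tgt - cur
        dist = np.linalg.norm(direction)
        over = tgt + cfg.overshoot_gain(s) * dist * direction / (dist + 1e-9)
        out_path = min_jerk(cur, over, move)
        back = min_jerk(over, tgt, settle)
        traj = np.vstack([out_path, back[1:]])
        end = min(T, start + len(traj))
        marker[start:end] = traj[:end - start]
        if end < T:
            marker[end:] = tgt
        cur = tgt.copy()
    # intention tremor: 2-5 Hz noise gated by movement speed (with a small
    # postural floor), so the tremor loads the reach itself.  Sign-change
    # counts are amplitude-blind, so severity must shift the *fraction* of
    # movement samples where tremor outweighs the smooth reach; a white
    # measurement-noise term would mask that, hence the narrowband-only model.
    speed = np.linalg.norm(np.gradient(marker, axis=0), axis=1)
    envelope = 0.15 + 0.85 * np.sqrt(speed / (speed.max() + 1e-12))
    tremor = np.column_stack([_narrowband(T, fs, rng), _narrowband(T, fs, rng)])
    marker += cfg.tremor_amp(s) * envelope[:, None] * tremor
    marker += cfg.marker_noise_px * rng.standard_normal((T, 2))
    return FctTrial(hand=hand, marker_xy=marker, target_events=events,
                    target_radius=cfg.target_radius_px, sample_rate=fs)


def simulate_ftt(cfg: GeneratorConfig, s: float, hand: str,
                 rng: np.random.Generator) -> ImuRecording:
    fs = IMU_SAMPLE_RATE
    T = int(round(cfg.ftt_duration_s * fs))
    t = np.arange(T) / fs
    cv = cfg.iti_cv(s)
    shape = 1.0 / cv ** 2
    taps = [0.3]
    while taps[-1] < cfg.ftt_duration_s - 0.3:
        taps.append(taps[-1] + rng.gamma(shape, cfg.mean_iti_s / shape))
    taps = np.array(taps[:-1])

    # zero-mean biphasic impact pulse per contact (a sharp deceleration-
    # rebound transient), riding on a gentle sub-threshold vertical
    # oscillation; zero mean keeps the band-pass from shifting the baseline
    z = np.zeros(T)
    sig = cfg.tap_impact_width_s
    for tk in taps:
        u = (t - tk) / sig
        z += cfg.tap_impact_amp * u * np.exp(-0.5 * u ** 2)
    for a, b in zip(taps[:-1], taps[1:]):
        seg = (t >= a) & (t < b)
        z[seg] += -cfg.tap_osc_amp * np.sin(np.pi * (t[seg] - a) / (b - a))

    tex = cfg.complexity(s)
    base = 0.3 * np.sin(2 * np.pi * 2.5 * t)
    noise = lambda: rng.standard_normal(T)  # noqa: E731
    accel = np.column_stack([
        base + 0.35 * tex * noise(),
        0.5 * base + 0.25 * tex * noise(),
        z + 0.15 * tex * noise(),
    ])
    gyro = np.column_stack([
        0.4 * base + 0.30 * tex * noise(),
        0.2 * base + 0.15 * tex * noise(),
        0.2 * base + 0.15 * tex * noise(),
    ])
    accel += cfg.imu_noise_sd * rng.standard_normal((T, 3))
    gyro += cfg.imu_noise_sd * rng.standard_normal((T, 3))
    return ImuRecording(test="FTT", hand=hand, accel=accel, gyro=gyro,
                        sample_rate=fs)


def _oscillatory(cfg: GeneratorConfig, s: float, hand: str, test: str,
                 rng: np.random.Generator,
                 nuisance_sd: float = 0.0) -> ImuRecording:
    """Shared FNT/DDKT model: primary-axis (Y) oscillation, X/Z leakage.

    ``nuisance_sd`` adds severity-independent log-normal subject variability
    to amplitude and leakage (rapid alternating movement is idiosyncratic
    even in healthy subjects), diluting the test's discriminative signal.
    """
    fs = IMU_SAMPLE_RATE
    T = int(round(cfg.osc_duration_s * fs))
    t = np.arange(T) / fs
    f0 = cfg.primary_osc_freq(s)
    amp = cfg.primary_osc_amp(s)
    leak = cfg.secondary_leak(s)
    if nuisance_sd > 0:
        amp *= np.exp(rng.normal(0.0, nuisance_sd))
        leak *= np.exp(rng.normal(0.0, nuisance_sd))
        f0 = float(np.clip(f0 + rng.normal(0.0, 0.4), 2.2, 4.8))
    phase = rng.uniform(0, 2 * np.pi)
    primary = amp * np.sin(2 * np.pi * f0 * t + phase) \
        + 0.15 * amp * _narrowband(T, fs, rng)

    def leak_axis() -> np.ndarray:
        return leak * _narrowband(T, fs, rng)

    gyro = np.column_stack([leak_axis(), primary, leak_axis()])
    accel = np.column_stack([
        leak_axis(),
        0.8 * amp * np.sin(2 * np.pi * f0 * t + phase + 0.4)
        + 0.12 * amp * _narrowband(T, fs, rng),
        leak_axis(),
    ])
    accel += cfg.imu_noise_sd * rng.standard_normal((T, 3))
    gyro += cfg.imu_noise_sd * rng.standard_normal((T, 3))
    return ImuRecording(test=test, hand=hand, accel=accel, gyro=gyro,
                        sample_rate=fs)


def simulate_fnt(cfg, s, hand, rng) -> ImuRecording:
    return _oscillatory(cfg, s, hand, "FNT", rng)


def simulate_ddkt(cfg, s, hand, rng) -> ImuRecording:
    return _oscillatory(cfg, s, hand, "DDKT", rng,
                        nuisance_sd=cfg.ddkt_nuisance_sd)


# --------------------------------------------------------------------------
# subjects and cohorts
# --------------------------------------------------------------------------

def simulate_subject(cfg: GeneratorConfig, s: float,
                     rng: np.random.Generator, subject_id: str = "S000",
                     group: str | None = None
                     ) -> tuple[SubjectRecord, dict[tuple[str, str], Recording]]:
    """One subject's full recording set plus clinical record at severity s."""
    if group is None:
        group = "control" if s == 0 else "ataxic"
    sara_ul = float(np.clip(np.round(3.0 * s + rng.normal(0, 0.5)), 0, 15))
    extra = max(0.0, np.round(5.0 * s + rng.normal(0, 2.0)))
    sara_total = float(np.clip(sara_ul + extra, sara_ul, 40))
    record = SubjectRecord(
        subject_id=subject_id, group=group,
        dominant_hand="R" if rng.random() < 0.9 else "L",
        age=float(np.round(rng.uniform(25, 75), 1)),
        sara_total=sara_total, sara_ul_sum=sara_ul,
        sara_ul_mean_rounded=int(round(sara_ul / 3.0)),
        severity=float(s))
    recs: dict[tuple[str, str], Recording] = {}
    for hand in ("L", "R"):
        recs[("FCT", hand)] = simulate_fct(cfg, s, hand, rng)
        recs[("FTT", hand)] = simulate_ftt(cfg, s, hand, rng)
        recs[("FNT", hand)] = simulate_fnt(cfg, s, hand, rng)
        recs[("DDKT", hand)] = simulate_ddkt(cfg, s, hand, rng)
    return record, recs


def simulate_subjects(cfg: GeneratorConfig
                      ) -> tuple[list[SubjectRecord],
                                 dict[RecordingKey, Recording]]:
    """In-memory cohort: n_subjects with the configured ataxic fraction.

    Controls sit at severity 0; ataxic severities are uniform over
    ``severity_range``.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ataxic = int(round(cfg.ataxic_fraction * cfg.n_subjects))
    sev = np.concatenate([
        rng.uniform(*cfg.severity_range, size=n_ataxic),
        np.zeros(cfg.n_subjects - n_ataxic)])
    subjects: list[SubjectRecord] = []
    recordings: dict[RecordingKey, Recording] = {}
    for i, s in enumerate(sev):
        sid = f"S{i:03d}"
        rec, per_test = simulate_subject(cfg, float(s), rng, subject_id=sid)
        subjects.append(rec)
        for (test, hand), r in per_test.items():
            recordings[(sid, test, hand)] = r
    return subjects, recordings


def simulate_cohort(cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write it to disk in the manifest + CSV layout.

    Returns the manifest path; latent severity travels with each subject as
    ground truth.
    """
    subjects, recordings = simulate_subjects(cfg)
    return write_cohort(subjects, recordings, out_dir)
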