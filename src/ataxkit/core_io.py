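"""Data model, feature catalog, cohort readers/writers, configuration and logging.

The package analyses four bedside tests of upper-limb cerebellar ataxia:

* FCT  - finger chase: a marker-tracked index finger pursues a target that
         jumps to a random screen position 20 times (2-D pixel trajectories,
         30 Hz).
* FTT  - finger tapping on a tabletop for ~15 s (wrist/hand IMU, 50 Hz).
* FNT  - finger-to-nose, repetitive reaching between nose and a fixed target.
* DDKT - dysdiadochokinesia, rapid alternating forearm pronation/supination.

Each recording is a CSV on disk; a JSON manifest ties recordings to subjects
and carries the clinical SARA scores (SARA-UL = the three upper-limb items,
0-15).  The feature catalog enumerates the 62 kinematic features extracted
downstream, each tagged with its test and its STAR domain (Stability, Timing,
Accuracy, Rhythmicity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ataxkit")

TESTS = ("FCT", "FTT", "FNT", "DDKT")
HANDS = ("L", "R")
STAR_DOMAINS = ("Stability", "Timing", "Accuracy", "Rhythmicity")

IMU_SAMPLE_RATE = 50.0  # Hz, tri-axial accelerometer + gyroscope
FCT_SAMPLE_RATE = 30.0  # Hz, 2-D marker/target trajectories (pixels)
FCT_N_TARGETS = 20      # target jumps in a complete finger-chase trial


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the extraction pipeline.

    Defaults follow the measurement protocol: 2nd-order 0.3-20 Hz band-pass
    on raw IMU channels, 6th-order 2-5 Hz band-pass before spectral peak
    features, fuzzy entropy with m=3 and r=0.2*std.
    """

    imu_band: tuple[float, float] = (0.3, 20.0)
    imu_order: int = 2
    spectral_band: tuple[float, float] = (2.0, 5.0)
    spectral_order: int = 6
    fuzzy_m: int = 3
    fuzzy_r_factor: float = 0.2
    tap_mad_factor: float = 3.0       # peak threshold = factor * MAD(|accel Z|)
    tap_min_separation_s: float = 0.150
    acalt_smooth_window: int = 5      # moving-average window before 2nd diff
    knn_k: int = 5
    qda_shrinkage: float | str = "auto"   # Ledoit-Wolf per-class covariance
    ridge_grid: tuple[float, ...] = tuple(float(10.0 ** e) for e in range(-3, 4))
    selection_alpha: float = 0.05
    selection_iters: int = 100
    subsample_fraction: float = 0.9
    top_k: int = 22                   # operating point for downstream models

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def setup_logging(level: int = logging.INFO, seed: int | None = None) -> None:
    """Configure structured logging; echoes the seed so runs are traceable."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    if seed is not None:
        logger.info("random seed = %d", seed)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

class ValidationError(ValueError):
    """A recording or manifest violates a type invariant."""


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                  # "control" | "ataxic"
    dominant_hand: str          # "L" | "R"
    age: float
    sara_total: float           # 0-40
    sara_ul_sum: float          # 0-15, sum of the three upper-limb items
    sara_ul_mean_rounded: int   # round(sara_ul_sum / 3), the 0-4 severity level
    severity: float | None = None   # latent ground truth (synthetic cohorts only)

    def __post_init__(self) -> None:
        if self.group not in ("control", "ataxic"):
            raise ValidationError(f"bad group {self.group!r}")
        if self.dominant_hand not in HANDS:
            raise ValidationError(f"bad hand {self.dominant_hand!r}")
        if self.sara_ul_sum > self.sara_total + 1e-9:
            raise ValidationError(
                f"{self.subject_id}: sara_ul_sum {self.sara_ul_sum} exceeds "
                f"sara_total {self.sara_total}")
        expected = int(round(self.sara_ul_sum / 3.0))
        if self.sara_ul_mean_rounded != expected:
            raise ValidationError(
                f"{self.subject_id}: sara_ul_mean_rounded must equal "
                f"round(sara_ul_sum/3) = {expected}")


@dataclass
class ImuRecording:
    """One hand's IMU stream for FTT, FNT or DDKT."""

    test: str
    hand: str
    accel: np.ndarray           # T x 3, axes X,Y,Z
    gyro: np.ndarray            # T x 3
    sample_rate: float = IMU_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.test not in ("FTT", "FNT", "DDKT"):
            raise ValidationError(f"bad IMU test {self.test!r}")
        if self.hand not in HANDS:
            raise ValidationError(f"bad hand {self.hand!r}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 \
                or self.accel.shape[1] != 3:
            raise ValidationError("accel and gyro must be equal-shape T x 3")
        if self.accel.shape[0] < 2 * self.sample_rate:
            raise ValidationError("recording shorter than 2 s")
        if np.isnan(self.accel).any() or np.isnan(self.gyro).any():
            raise ValidationError("NaN in IMU recording")


@dataclass
class FctTrial:
    """One hand's finger-chase trial: marker trajectory plus target jumps."""

    hand: str
    marker_xy: np.ndarray                       # T x 2, pixels
    target_events: list[tuple[int, float, float]]  # (onset_sample, x_px, y_px)
    target_radius: float                        # ra, pixels
    sample_rate: float = FCT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.marker_xy = np.asarray(self.marker_xy, dtype=float)
        if self.hand not in HANDS:
            raise ValidationError(f"bad hand {self.hand!r}")
        if self.marker_xy.ndim != 2 or self.marker_xy.shape[1] != 2:
            raise ValidationError("marker_xy must be T x 2")
        if np.isnan(self.marker_xy).any():
            raise ValidationError("NaN in marker trajectory")
        if self.target_radius <= 0 or self.sample_rate <= 0:
            raise ValidationError("target_radius and sample_rate must be positive")
        onsets = [int(e[0]) for e in self.target_events]
        if len(onsets) < 2:
            raise ValidationError("need at least 2 target events")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("target onsets must be strictly increasing")
        if onsets[-1] >= len(self.marker_xy):
            raise ValidationError("target onset beyond trajectory end")
        if len(onsets) != FCT_N_TARGETS:
            logger.warning("FCT trial has %d target events (complete trial has %d)",
                           len(onsets), FCT_N_TARGETS)

    @property
    def target_xy(self) -> np.ndarray:
        """Piecewise-constant T x 2 target trajectory (constant between jumps)."""
        out = np.zeros_like(self.marker_xy)
        onsets = [int(e[0]) for e in self.target_events]
        # before the first jump the target sits at its first position
        prev = 0
        pos = (self.target_events[0][1], self.target_events[0][2])
        for (onset, x, y) in self.target_events:
            out[prev:onset] = pos
            pos = (x, y)
            prev = onset
        out[prev:] = pos
        return out


# --------------------------------------------------------------------------
# feature catalog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str       # canonical "{Feature}_{Test}_{SignalAxis}_{Hand}"
    feature: str    # AcAlt, ReTi, KiDe, DTWEr, CITI, FuEn, RF, MR
    test: str
    signal: str     # PosX, Pos2D, AcX, GyX, AAcY, AngZ, Tap, ...
    hand: str
    star: str       # Stability | Timing | Accuracy | Rhythmicity


def _fct_specs(hand: str) -> list[FeatureSpec]:
    rows = [
        ("AcAlt", "PosX", "Stability"), ("AcAlt", "PosY", "Stability"),
        ("ReTi", "PosX", "Timing"), ("ReTi", "PosY", "Timing"),
        ("DTWEr", "PosX", "Accuracy"), ("DTWEr", "PosY", "Accuracy"),
        ("KiDe", "Pos2D", "Timing"),
    ]
    return [FeatureSpec(f"{f}_FCT_{s}_{hand}", f, "FCT", s, hand, star)
            for f, s, star in rows]


def _ftt_specs(hand: str) -> list[FeatureSpec]:
    rows = [
        ("CITI", "Tap", "Timing"),
        ("FuEn", "AcX", "Stability"),
        ("FuEn", "AcZ", "Rhythmicity"),
        ("FuEn", "GyX", "Rhythmicity"),
    ]
    return [FeatureSpec(f"{f}_FTT_{s}_{hand}", f, "FTT", s, hand, star)
            for f, s, star in rows]


def _fnt_specs(hand: str) -> list[FeatureSpec]:
    # angular acceleration: RF & MR on all three axes; X/Z are stability axes,
    # on the primary (Y) axis RF carries timing and MR rhythmicity
    rows = [
        ("RF", "AAcX", "Stability"), ("MR", "AAcX", "Stability"),
        ("RF", "AAcY", "Timing"), ("MR", "AAcY", "Rhythmicity"),
        ("RF", "AAcZ", "Stability"), ("MR", "AAcZ", "Stability"),
        # linear acceleration: RF & MR on X; RF only on Y and Z.  STAR tags
        # follow the same axis-role rule as the angular channels.
        ("RF", "AcX", "Stability"), ("MR", "AcX", "Stability"),
        ("RF", "AcY", "Timing"),
        ("RF", "AcZ", "Stability"),
    ]
    return [FeatureSpec(f"{f}_FNT_{s}_{hand}", f, "FNT", s, hand, star)
            for f, s, star in rows]


def _ddkt_specs(hand: str) -> list[FeatureSpec]:
    rows = [
        ("RF", "AngX", "Stability"), ("MR", "AngX", "Stability"),
        ("RF", "AngZ", "Stability"), ("MR", "AngZ", "Stability"),
        ("RF", "AcX", "Stability"), ("MR", "AcX", "Stability"),
        ("RF", "AcZ", "Stability"), ("MR", "AcZ", "Stability"),
        ("RF", "AAcY", "Timing"), ("MR", "AAcY", "Rhythmicity"),
    ]
    return [FeatureSpec(f"{f}_DDKT_{s}_{hand}", f, "DDKT", s, hand, star)
            for f, s, star in rows]


def catalog_features() -> list[FeatureSpec]:
    """The full ordered 62-feature catalog: FCT 14, FTT 8, FNT 20, DDKT 20.

    Order is deterministic: tests in protocol order, left hand before right,
    features in the catalog's row order within each test.
    """
    specs: list[FeatureSpec] = []
    for maker in (_fct_specs, _ftt_specs, _fnt_specs, _ddkt_specs):
        for hand in HANDS:
            specs.extend(maker(hand))
    return specs


def catalog_frame() -> pd.DataFrame:
    """Catalog as a DataFrame indexed by feature name with tag columns."""
    specs = catalog_features()
    return pd.DataFrame(
        {"feature": [s.feature for s in specs],
         "test": [s.test for s in specs],
         "signal": [s.signal for s in specs],
         "hand": [s.hand for s in specs],
         "star": [s.star for s in specs]},
        index=pd.Index([s.name for s in specs], name="name"),
    )


# --------------------------------------------------------------------------
# cohort I/O: one CSV per recording + one JSON manifest per cohort
# --------------------------------------------------------------------------

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
FCT_COLUMNS = ["t", "mx", "my"]
EVENT_COLUMNS = ["onset_sample", "x_px", "y_px"]

RecordingKey = tuple[str, str, str]  # (subject_id, test, hand)
Recording = ImuRecording | FctTrial


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parse failures with path
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df[columns].isna().any().any():
        bad = int(df[columns].isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValidationError(f"{path}: NaN value at line {bad}")
    return df


def _load_recording(entry: Mapping, base: Path) -> tuple[RecordingKey, Recording]:
    test, hand = entry["test"], entry["hand"]
    path = base / entry["path"]
    if test == "FCT":
        df = _read_csv(path, FCT_COLUMNS)
        ev = _read_csv(base / entry["events_path"], EVENT_COLUMNS)
        events = [(int(r.onset_sample), float(r.x_px), float(r.y_px))
                  for r in ev.itertuples()]
        rec: Recording = FctTrial(
            hand=hand,
            marker_xy=df[["mx", "my"]].to_numpy(),
            target_events=events,
            target_radius=float(entry["target_radius"]),
            sample_rate=float(entry.get("sample_rate", FCT_SAMPLE_RATE)),
        )
    else:
        df = _read_csv(path, IMU_COLUMNS)
        rec = ImuRecording(
            test=test,
            hand=hand,
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            sample_rate=float(entry.get("sample_rate", IMU_SAMPLE_RATE)),
        )
    return (entry["subject_id"], test, hand), rec


def read_cohort(manifest_path: str | Path
                ) -> tuple[list[SubjectRecord], dict[RecordingKey, Recording]]:
    """Load a cohort manifest and all recordings it references.

    Subjects with missing tests are retained; the gap shows up as an absent
    key in the recordings dict and is logged.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    subjects = []
    recordings: dict[RecordingKey, Recording] = {}
    for sub in manifest["subjects"]:
        rec_entries = sub.pop("recordings", [])
        subjects.append(SubjectRecord(**sub))
        for entry in rec_entries:
            entry = dict(entry, subject_id=sub["subject_id"])
            key, rec = _load_recording(entry, base)
            recordings[key] = rec
        present = {(t, h) for (s, t, h) in recordings if s == sub["subject_id"]}
        for test in TESTS:
            for hand in HANDS:
                if (test, hand) not in present:
                    logger.warning("subject %s missing %s/%s",
                                   sub["subject_id"], test, hand)
    return subjects, recordings


def write_cohort(subjects: Iterable[SubjectRecord],
                 recordings: Mapping[RecordingKey, Recording],
                 out_dir: str | Path) -> Path:
    """Write a cohort to disk in the manifest + per-recording CSV layout.

    Returns the manifest path; ``read_cohort`` of that path round-trips all
    values within float formatting tolerance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries_by_subject: dict[str, list[dict]] = {}
    for (sid, test, hand), rec in sorted(recordings.items()):
        stem = f"{sid}_{test}_{hand}"
        entry: dict = {"test": test, "hand": hand, "path": f"{stem}.csv",
                       "sample_rate": rec.sample_rate}
        if isinstance(rec, FctTrial):
            t = np.arange(len(rec.marker_xy)) / rec.sample_rate
            pd.DataFrame({"t": t, "mx": rec.marker_xy[:, 0],
                          "my": rec.marker_xy[:, 1]}).to_csv(
                out_dir / f"{stem}.csv", index=False)
            pd.DataFrame(rec.target_events,
                         columns=EVENT_COLUMNS).to_csv(
                out_dir / f"{stem}_events.csv", index=False)
            entry["events_path"] = f"{stem}_events.csv"
            entry["target_radius"] = rec.target_radius
        else:
            t = np.arange(len(rec.accel)) / rec.sample_rate
            pd.DataFrame({"t": t,
                          "ax": rec.accel[:, 0], "ay": rec.accel[:, 1],
                          "az": rec.accel[:, 2],
                          "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1],
                          "gz": rec.gyro[:, 2]}).to_csv(
                out_dir / f"{stem}.csv", index=False)
        entries_by_subject.setdefault(sid, []).append(entry)

    manifest = {"subjects": []}
    for sub in subjects:
        d = asdict(sub)
        d["recordings"] = entries_by_subject.get(sub.subject_id, [])
        manifest["subjects"].append(d)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path
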