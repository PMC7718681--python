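"""Generator contracts: determinism, cohort composition, calibration anchors
and the monotone response of every severity-sensitive feature family."""

import json

import numpy as np
import pytest
from scipy.stats import spearmanr

import ataxkit as ak
from ataxkit.synth_cohort import (GeneratorConfig, simulate_fct, simulate_ftt,
                                  simulate_subject)

# feature families that must respond monotonically to severity, with sign
MONOTONE_FAMILIES = {
    "KiDe_FCT_Pos2D": -1,
    "ReTi_FCT_PosX": +1, "ReTi_FCT_PosY": +1,
    "DTWEr_FCT_PosX": +1, "DTWEr_FCT_PosY": +1,
    "AcAlt_FCT_PosX": +1, "AcAlt_FCT_PosY": +1,
    "FuEn_FTT_AcX": -1, "FuEn_FTT_AcZ": -1, "FuEn_FTT_GyX": -1,
    "MR_FNT_AAcY": -1,
    "CITI_FTT_Tap": +1,
}


class TestDeterminism:
    def test_same_seed_identical_recordings(self):
        cfg = GeneratorConfig()
        r1, s1 = simulate_subject(cfg, 1.5, np.random.default_rng(11), "A")
        r2, s2 = simulate_subject(cfg, 1.5, np.random.default_rng(11), "A")
        assert r1 == r2
        for key in s1:
            a, b = s1[key], s2[key]
            if isinstance(a, ak.FctTrial):
                np.testing.assert_array_equal(a.marker_xy, b.marker_xy)
            else:
                np.testing.assert_array_equal(a.accel, b.accel)
                np.testing.assert_array_equal(a.gyro, b.gyro)

    def test_manifest_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=2, seed=5)
        m1 = ak.simulate_cohort(cfg, tmp_path / "a")
        m2 = ak.simulate_cohort(cfg, tmp_path / "b")
        assert m1.read_text() == m2.read_text()


class TestCohortComposition:
    def test_default_group_sizes(self):
        cfg = GeneratorConfig(n_subjects=55)
        subjects, _ = ak.simulate_subjects(cfg)
        groups = [s.group for s in subjects]
        assert groups.count("ataxic") == 41
        assert groups.count("control") == 14

    def test_simulated_cohort_reads_back_validly(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=3, seed=2)
        manifest = ak.simulate_cohort(cfg, tmp_path / "c")
        subjects, recordings = ak.read_cohort(manifest)
        assert len(subjects) == 3
        assert len(recordings) == 3 * 4 * 2
        raw = json.loads(manifest.read_text())
        assert all("severity" in s for s in raw["subjects"])
        for s in subjects:
            assert s.sara_ul_sum <= s.sara_total
            assert s.sara_ul_mean_rounded == round(s.sara_ul_sum / 3.0)

    def test_controls_sit_at_zero_severity(self):
        cfg = GeneratorConfig(n_subjects=12, ataxic_fraction=0.5, seed=4)
        subjects, _ = ak.simulate_subjects(cfg)
        for s in subjects:
            if s.group == "control":
                assert s.severity == 0.0
                assert s.sara_ul_sum <= 1.0

    def test_knobs_monotone_in_severity(self):
        cfg = GeneratorConfig()
        grid = np.linspace(0.0, 3.0, 7)
        for knob, sign in [("reaction_delay_ms", +1), ("overshoot_gain", +1),
                           ("tremor_amp", +1), ("iti_cv", +1),
                           ("complexity", -1), ("primary_osc_amp", -1),
                           ("secondary_leak", +1)]:
            vals = np.array([getattr(cfg, knob)(s) for s in grid])
            assert np.all(sign * np.diff(vals) >= 0), knob


class TestCalibrationAnchors:
    def test_reaction_time_group_means(self):
        """Control cohorts land near 750 ms, severe cohorts near 1100 ms."""
        cfg = GeneratorConfig()
        means = {}
        for label, s in (("control", 0.0), ("ataxic", 2.5)):
            vals = []
            for seed in range(6):
                trial = simulate_fct(cfg, s, "R", np.random.default_rng(seed))
                feats = ak.extract_fct_features(trial)
                vals.append(feats["ReTi_FCT_PosX_R"])
            means[label] = np.mean(vals)
        assert means["control"] == pytest.approx(750.0, abs=100.0)
        assert means["ataxic"] == pytest.approx(1100.0, abs=150.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_complexity_loss_in_tapping_entropy(self, seed):
        cfg = GeneratorConfig()
        lo = ak.extract_imu_features(
            simulate_ftt(cfg, 0.0, "R", np.random.default_rng(seed)))
        hi = ak.extract_imu_features(
            simulate_ftt(cfg, 2.5, "R", np.random.default_rng(seed)))
        assert hi["FuEn_FTT_AcX_R"] < lo["FuEn_FTT_AcX_R"]


class TestSeverityResponse:
    def test_monotone_families_on_cohort(self, features100, cohort100):
        """Each severity-sensitive family correlates |rho| >= 0.5 with the
        latent severity, in its clinically expected direction."""
        _, subjects, _ = cohort100
        _, feats = features100
        sev = np.array([s.severity for s in subjects])
        for family, sign in MONOTONE_FAMILIES.items():
            for hand in ("L", "R"):
                col = f"{family}_{hand}"
                rho = spearmanr(feats[col], sev).statistic
                assert sign * rho >= 0.5, f"{col}: rho={rho:.2f}"

    def test_severity_is_recoverable(self, pipeline100):
        subjects, result = pipeline100
        true_level = np.minimum(
            [s.sara_ul_mean_rounded for s in subjects], 3)
        pred_level = result.severity.predicted_level.to_numpy()
        within_one = np.mean(np.abs(pred_level - true_level) <= 1)
        assert within_one >= 0.9
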