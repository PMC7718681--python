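"""Finger-chase features against independent oracles.

The DTW oracle enumerates every monotone warping path recursively; the
reaction-time oracle is an exhaustive lag scan over constructed shifts; the
kinematic-delay cases are hand-built trials with known entry times.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ataxkit as ak
from ataxkit.features_fct import (accel_alterations, dtw_error,
                                  kinematic_delay, reaction_time)
from ataxkit.synth_cohort import GeneratorConfig, min_jerk, simulate_fct


def dtw_path_oracle(a, b):
    """Minimum path cost by brute-force enumeration of all monotone paths."""
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        if i + 1 < len(a):
            walk(i + 1, j, acc)
        if j + 1 < len(b):
            walk(i, j + 1, acc)
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwError:
    def test_identical_sequences_zero(self):
        assert dtw_error([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_frozen_examples(self):
        assert dtw_error([0, 1, 2], [1, 2, 3]) == 2.0
        assert dtw_error([0, 0, 0], [1, 1, 1]) == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_error([], [1.0])

    def test_exhaustive_oracle_short_sequences(self):
        # every pair of length <= 3 sequences over {0, 1, 2}
        for la in (1, 2, 3):
            for a in itertools.product((0.0, 1.0, 2.0), repeat=la):
                for b in itertools.product((0.0, 1.0, 2.0), repeat=la):
                    assert dtw_error(a, b) == pytest.approx(
                        dtw_path_oracle(a, b))

    def test_oracle_random_longer_sequences(self, rng):
        for _ in range(120):
            la, lb = rng.integers(4, 7, size=2)
            a = rng.integers(0, 3, size=la).astype(float)
            b = rng.integers(0, 3, size=lb).astype(float)
            assert dtw_error(a, b) == pytest.approx(dtw_path_oracle(a, b))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8),
           st.lists(st.integers(0, 5), min_size=1, max_size=8))
    def test_symmetry(self, a, b):
        assert dtw_error(a, b) == pytest.approx(dtw_error(b, a))


class TestReactionTime:
    def test_zero_lag_for_identical_series(self, rng):
        x = np.repeat(rng.standard_normal(10), 30)
        assert reaction_time(x, x, 30.0) == 0.0

    def test_constructed_shift_recovered(self, rng):
        target = np.repeat(rng.standard_normal(12), 25)
        marker = np.roll(target, 6)
        assert reaction_time(marker, target, 30.0) == pytest.approx(200.0)

    @pytest.mark.parametrize("shift", range(0, 31, 3))
    def test_shift_scan(self, shift, rng):
        target = np.repeat(rng.standard_normal(12), 30)
        marker = np.roll(target, shift)
        lag_ms = reaction_time(marker, target, 30.0)
        assert abs(lag_ms - shift / 30.0 * 1000.0) <= 1 / 30.0 * 1000.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reaction_time(np.ones(50), np.ones(50), 30.0)


def _entry_trial(entry_sample: int, total: int = 150,
                 di: float = 80.0, ra: float = 10.0) -> ak.FctTrial:
    """Marker teleports onto the target exactly at `entry_sample`."""
    marker = np.zeros((total, 2))
    marker[entry_sample:, 0] = di
    events = [(0, 0.0, 0.0), (30, di, 0.0)]
    return ak.FctTrial(hand="R", marker_xy=marker, target_events=events,
                       target_radius=ra, sample_rate=30.0)


class TestKinematicDelay:
    def test_hand_computed_throughput(self):
        # di = 80 px, ra = 10 px -> ID = 3 bits; entry 1.5 s after onset
        trial = _entry_trial(entry_sample=30 + 44)
        assert kinematic_delay(trial) == pytest.approx(3.0 / 1.5)

    def test_doubling_movement_time_halves_kide(self):
        fast = kinematic_delay(_entry_trial(30 + 44, total=200))
        slow = kinematic_delay(_entry_trial(30 + 89, total=200))
        assert slow == pytest.approx(fast / 2.0)

    def test_zero_difficulty_reach_contributes_zero(self):
        trial = _entry_trial(entry_sample=40, di=10.0, ra=10.0)
        assert kinematic_delay(trial) == 0.0

    def test_unreached_target_excluded(self):
        marker = np.zeros((150, 2))  # never approaches the target
        trial = ak.FctTrial(hand="R", marker_xy=marker,
                            target_events=[(0, 0.0, 0.0), (30, 500.0, 0.0)],
                            target_radius=10.0, sample_rate=30.0)
        with pytest.raises(ValueError):
            kinematic_delay(trial)


class TestAccelAlterations:
    def test_constant_velocity_zero(self):
        x = np.linspace(0, 100, 90)
        assert accel_alterations(x, 30.0, smooth_window=1) == 0.0

    def test_min_jerk_matches_second_difference_oracle(self):
        reach = min_jerk(np.array([0.0]), np.array([100.0]), 40)[:, 0]
        got = accel_alterations(reach, 30.0, smooth_window=1)
        acc = np.diff(reach, n=2)
        signs = np.sign(acc)
        signs = signs[signs != 0]
        assert got == float(np.sum(signs[1:] != signs[:-1]))

    def test_tremor_increases_count(self):
        t = np.arange(90) / 30.0
        reach = min_jerk(np.array([0.0]), np.array([100.0]), 90)[:, 0]
        base = accel_alterations(reach, 30.0)
        shaky = accel_alterations(reach + 10.0 * np.sin(2 * np.pi * 8 * t),
                                  30.0)
        assert shaky > base


class TestSeverityDirections:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_four_features_move_as_severity_increases(self, seed):
        """KiDe falls; ReTi, DTWEr and AcAlt rise from severity 0 to 2.5."""
        cfg = GeneratorConfig()
        lo = ak.extract_fct_features(
            simulate_fct(cfg, 0.0, "R", np.random.default_rng(seed)))
        hi = ak.extract_fct_features(
            simulate_fct(cfg, 2.5, "R", np.random.default_rng(seed)))
        assert hi["KiDe_FCT_Pos2D_R"] < lo["KiDe_FCT_Pos2D_R"]
        for stem in ("ReTi", "DTWEr", "AcAlt"):
            for ax in ("X", "Y"):
                name = f"{stem}_FCT_Pos{ax}_R"
                assert hi[name] > lo[name], name
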