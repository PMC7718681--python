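"""Tapping and spectral features against direct oracles.

The fuzzy-entropy oracle is a literal double loop over template pairs; the
spectral oracle is tone construction at known frequencies.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ataxkit as ak
from ataxkit.features_imu import (TapSeries, citi, detect_taps, fuzzy_entropy,
                                  rf_mr)

FS = 50.0


def spike_train(n_spikes=20, spacing_s=0.4, fs=FS, amp=5.0,
                width_samples=1.5):
    """Gaussian contact transients at exact spacing (finite width, as a real
    impact has, which is what keeps the MAD threshold above the baseline)."""
    t_end = (n_spikes + 1) * spacing_s
    n = int(t_end * fs)
    x = np.zeros(n)
    idx = np.arange(n)
    for k in range(n_spikes):
        centre = int(round((k + 1) * spacing_s * fs))
        x += amp * np.exp(-0.5 * ((idx - centre) / width_samples) ** 2)
    return x


class TestDetectTaps:
    def test_regular_train_recovered(self):
        taps = detect_taps(spike_train(), FS)
        assert len(taps.tap_times) == 20
        np.testing.assert_allclose(taps.iti, 0.4, atol=1e-9)

    def test_subthreshold_noise_ignored(self, rng):
        spikes = spike_train(amp=5.0)
        noise = 0.03 * rng.standard_normal(spikes.size)
        x = spikes + noise
        # oracle: verify the noise really is below the detector's threshold
        thr = 3.0 * np.median(np.abs(np.abs(x) - np.median(np.abs(x))))
        assert np.max(np.abs(noise)) < thr
        taps = detect_taps(x, FS)
        assert len(taps.tap_times) == 20
        np.testing.assert_allclose(taps.iti, 0.4, atol=0.03)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="insufficient taps"):
            detect_taps(np.zeros(750), FS)


class TestCiti:
    def test_regular_intervals_zero(self):
        taps = TapSeries(np.arange(10) * 0.4)
        assert citi(taps) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # ITIs 0.5, 0.5, 1.0 -> sample SD 0.288675 / mean 0.666667 = 0.433
        taps = TapSeries(np.array([0.0, 0.5, 1.0, 2.0]))
        assert citi(taps) == pytest.approx(0.4330127, abs=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_time_rescaling_invariance(self, scale):
        base = np.array([0.0, 0.4, 0.9, 1.2, 1.9])
        assert citi(TapSeries(base * scale)) == pytest.approx(
            citi(TapSeries(base)), rel=1e-9)


def fuzzy_entropy_oracle(y, m, r):
    """Literal double-loop evaluation over all template pairs."""
    def phi(mm):
        n = len(y) - mm
        tpl = [np.asarray(y[i:i + mm]) - np.mean(y[i:i + mm])
               for i in range(n)]
        total = 0.0
        for p in range(n):
            inner = 0.0
            for q in range(n):
                if p == q:
                    continue
                d = np.max(np.abs(tpl[p] - tpl[q]))
                inner += np.exp(-((d / r) ** 2))
            total += inner / (n - 1)
        return total / n

    return np.log(phi(m)) - np.log(phi(m + 1))


class TestFuzzyEntropy:
    def test_constant_series_zero(self):
        assert fuzzy_entropy(np.ones(50), m=3, r=0.5) == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        for seed in range(20):
            y = np.random.default_rng(seed).standard_normal(10)
            r = 0.2 * np.std(y)
            assert fuzzy_entropy(y, m=3, r=r) == pytest.approx(
                fuzzy_entropy_oracle(y, 3, r), abs=1e-10)

    def test_white_noise_more_irregular_than_sine(self):
        # complexity-loss direction: stereotyped movement scores lower
        t = np.arange(750) / FS
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * 2.0 * t)
        for seed in range(10):
            noise = np.random.default_rng(seed).standard_normal(750)
            assert fuzzy_entropy(noise) > fuzzy_entropy(sine)

    def test_non_negative(self, rng):
        for _ in range(10):
            y = rng.standard_normal(150)
            assert fuzzy_entropy(y) >= 0.0

    def test_affine_invariance_with_relative_radius(self, rng):
        y = rng.standard_normal(200)
        base = fuzzy_entropy(y)
        assert fuzzy_entropy(3.0 * y + 7.0) == pytest.approx(base, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_entropy(np.arange(4.0), m=3)


class TestRfMr:
    def test_single_tone_location(self):
        t = np.arange(int(10 * FS)) / FS
        sf = rf_mr(2.0 * np.sin(2 * np.pi * 3.0 * t), FS)
        assert abs(sf.rf - 3.0) <= FS / 1024  # one FFT bin
        assert sf.mr == pytest.approx(2.0, rel=0.05)

    def test_amplitude_linearity(self):
        t = np.arange(int(10 * FS)) / FS
        a = rf_mr(np.sin(2 * np.pi * 3.0 * t), FS)
        b = rf_mr(2.0 * np.sin(2 * np.pi * 3.0 * t), FS)
        assert b.rf == a.rf
        assert b.mr == pytest.approx(2.0 * a.mr, rel=1e-9)

    def test_dominant_of_two_tones(self):
        t = np.arange(int(10 * FS)) / FS
        x = 2.0 * np.sin(2 * np.pi * 2.5 * t) + np.sin(2 * np.pi * 4.0 * t)
        assert abs(rf_mr(x, FS).rf - 2.5) <= FS / 1024

    @pytest.mark.parametrize("freq", np.arange(2.0, 5.01, 0.25))
    def test_tone_sweep_within_one_bin(self, freq):
        t = np.arange(int(10 * FS)) / FS
        sf = rf_mr(np.sin(2 * np.pi * freq * t), FS)
        nfft = 1024
        assert abs(sf.rf - freq) <= FS / nfft

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            rf_mr(np.zeros(500), FS)


class TestExtractCounts:
    @pytest.mark.parametrize("test,expected", [
        ("FTT", 4), ("FNT", 10), ("DDKT", 10)])
    def test_features_per_hand(self, test, expected, rng):
        cfg = ak.GeneratorConfig()
        sim = {"FTT": ak.synth_cohort.simulate_ftt,
               "FNT": ak.synth_cohort.simulate_fnt,
               "DDKT": ak.synth_cohort.simulate_ddkt}[test]
        feats = ak.extract_imu_features(sim(cfg, 1.0, "L", rng))
        assert len(feats) == expected
        assert all(name.endswith("_L") and test in name for name in feats)
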