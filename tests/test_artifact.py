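"""Entropy features, ApEn oracle equivalence, channel MLP, 7-channel rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepmat import synthdata as sd
from sleepmat.artifact import (ArtifactDetector, approx_entropy,
                               approx_entropy_naive, channel_features,
                               energy_entropy, flag_sample, sample_features,
                               train_artifact_mlp)
from sleepmat.decompose import decompose_minute


class TestEnergyEntropy:
    def test_identical_windows_reach_ln_k(self):
        # 10 identical windows -> uniform energy distribution -> ln(10)
        x = np.tile(np.array([1.0, -2.0, 0.5, 1.5]), 10)
        assert energy_entropy(x, window=4, step=4) == pytest.approx(np.log(10))

    def test_hand_enumerated_two_windows(self):
        # windows [1,1] and [2,2]: energies [2, 8], p = [0.2, 0.8],
        # H = -(0.2 ln 0.2 + 0.8 ln 0.8) = 0.5004 nats
        val = energy_entropy(np.array([1.0, 1.0, 2.0, 2.0]), 2, 2)
        assert val == pytest.approx(0.500402, abs=1e-6)

    def test_all_zero_signal_defined_as_zero(self):
        assert energy_entropy(np.zeros(100), 10, 5) == 0.0

    def test_partial_windows_dropped(self):
        # length 11, window 4, step 4 -> 2 full windows only
        x = np.ones(11)
        assert energy_entropy(x, 4, 4) == pytest.approx(np.log(2))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            energy_entropy(np.ones(10), 20, 1)


class TestApproxEntropy:
    def test_constant_series_is_perfectly_regular(self):
        assert approx_entropy(np.full(300, 2.5)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_reference(self, seed):
        # exact counting algorithm vs brute-force O(N^2) double loop
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 601))
        x = rng.standard_normal(n)
        assert approx_entropy(x) == pytest.approx(approx_entropy_naive(x),
                                                  abs=1e-9)

    def test_sinusoid_more_regular_than_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(400)
        sin_vals, noise_vals = [], []
        for trial in range(25):
            phase = rng.uniform(0, 2 * np.pi)
            s = np.sin(2 * np.pi * 0.02 * t + phase)
            w = rng.standard_normal(400)
            w *= s.std() / w.std()
            sin_vals.append(approx_entropy(s))
            noise_vals.append(approx_entropy(w))
        assert np.median(sin_vals) < np.median(noise_vals)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            approx_entropy(np.array([1.0, 2.0]), m=2)


class TestChannelFeatures:
    def test_zero_channel_gives_zero_features(self):
        d = decompose_minute(np.zeros((32, 6000)))
        f = channel_features(d, 0)
        np.testing.assert_array_equal(f.as_array(), np.zeros(6))

    def test_feature_vector_order_and_length(self, clean_decomposed):
        f = channel_features(clean_decomposed, 3)
        arr = f.as_array()
        assert arr.shape == (6,)
        assert arr[0] == f.resp_ent_energy
        assert arr[3] == f.resp_ent_approx

    def test_invalid_channel_rejected(self, clean_decomposed):
        with pytest.raises(ValueError):
            channel_features(clean_decomposed, 32)

    def test_contamination_shifts_entropy_features(self, default_profile,
                                                   supine_template):
        # Bursty artifacts concentrate energy (energy entropies drop) and
        # disrupt respiratory regularity (resp ApEn rises).  The deviation
        # ApEn *drops*: bursts inflate the similarity radius r = 0.2 SD,
        # and clipping plateaus are self-similar.  Strict separation in
        # >= 90% of paired trials.
        n = 20
        lower = np.zeros(6)
        higher = np.zeros(6)
        from sleepmat.decompose import BandpassDecomposer
        dec = BandpassDecomposer()
        for seed in range(n):
            mc = sd.synth_minute(default_profile, supine_template, False, seed)
            mm = sd.synth_minute(default_profile, supine_template, True, seed)
            ch = int(np.flatnonzero(mm.per_channel_movement)[0])
            fc = channel_features(dec.transform([mc])[0], ch).as_array()
            fm = channel_features(dec.transform([mm])[0], ch).as_array()
            lower += fm < fc
            higher += fm > fc
        for idx in (0, 1, 2, 5):       # energy entropies and dev ApEn drop
            assert lower[idx] / n >= 0.9
        assert higher[3] / n >= 0.9    # resp ApEn rises


def _toy_features(n=120, seed=0):
    rng = np.random.default_rng(seed)
    clean = rng.normal(0.0, 0.3, size=(n, 6))
    contaminated = rng.normal(3.0, 0.3, size=(n, 6))
    X = np.vstack([clean, contaminated])
    y = np.array([False] * n + [True] * n)
    return X, y


class TestArtifactMLP:
    def test_separable_features_learned_perfectly(self):
        X, y = _toy_features()
        det = ArtifactDetector(random_state=0).fit(X, y)
        assert (det.predict(X) == y).all()

    def test_single_class_rejected(self):
        X, _ = _toy_features()
        with pytest.raises(ValueError):
            ArtifactDetector().fit(X, np.zeros(len(X), dtype=bool))

    def test_decision_threshold_is_half(self):
        X, y = _toy_features()
        det = ArtifactDetector(random_state=0).fit(X, y)
        proba = det.predict_proba(X)[:, 1]
        np.testing.assert_array_equal(det.predict(X), proba > 0.5)

    def test_functional_wrapper(self):
        X, y = _toy_features(n=40)
        det = train_artifact_mlp(list(X), y, seed=1)
        assert (det.predict(X) == y).mean() > 0.95


class TestFlagSample:
    @pytest.mark.parametrize("count,expected", [(0, False), (6, False),
                                                (7, True), (32, True)])
    def test_seven_channel_rule(self, count, expected):
        flags = np.zeros(32, dtype=bool)
        flags[:count] = True
        decision = flag_sample(flags)
        assert decision.sample_flag is expected
        assert decision.interfered_count == count

    def test_wrong_flag_count_rejected(self):
        with pytest.raises(ValueError):
            flag_sample(np.zeros(16, dtype=bool))

    @given(st.lists(st.booleans(), min_size=32, max_size=32),
           st.integers(min_value=0, max_value=31))
    @settings(max_examples=50, deadline=None)
    def test_adding_a_flag_never_unflags(self, flags, idx):
        flags = np.array(flags)
        before = flag_sample(flags).sample_flag
        flags[idx] = True
        after = flag_sample(flags).sample_flag
        assert after or not before
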