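"""Synthetic generators: toy LM, copula features, stimulus and EEG."""

import numpy as np
import pandas as pd
import pytest

from f0track.lagged import LagGrid
from f0track.stimulus import (
    extract_fundamental_waveform,
    pitch_band_from_percentiles,
)
from f0track.synthetic import (
    DEFAULT_FEATURE_CORRELATION,
    SyntheticSpec,
    ToyLanguageModel,
    correlated_word_features,
    generate_dataset,
    generate_word_stream,
    probability_source_from_features,
    simulate_eeg,
    synthesize_stimulus,
    word_gains,
)
from f0track.words import FEATURE_ORDER, information_features


class TestToyLanguageModel:
    def test_uniform_chain_closed_forms(self):
        """Uniform 4-token chain: every surprisal ln 4, precision 1/ln 4."""
        lm = ToyLanguageModel.uniform(4)
        stream = generate_word_stream(lm, 200, seed=0)
        assert np.allclose(stream["surprisal"], np.log(4))
        assert np.allclose(stream["precision"], 1 / np.log(4))
        assert not stream["entropy_clamped"].any()

    def test_deterministic_chain_clamped(self):
        """A deterministic cycle: zero surprisal and entropy, precision
        clamped and flagged."""
        P = np.roll(np.eye(4), 1, axis=1)
        lm = ToyLanguageModel([f"w{i}" for i in range(4)], P)
        stream = generate_word_stream(lm, 50, seed=0)
        assert np.allclose(stream["surprisal"].iloc[1:], 0.0)
        assert np.allclose(stream["entropy"].iloc[1:], 0.0)
        assert stream["entropy_clamped"].iloc[1:].all()
        assert np.allclose(stream["precision"].iloc[1:], 1e6)

    def test_stationary_distribution(self):
        lm = ToyLanguageModel.random(6, seed=1)
        pi = lm.stationary
        assert np.allclose(pi @ lm.transition, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_mean_surprisal_matches_entropy_rate(self):
        """AEP check: mean surprisal over 10,000 words is within 3 SE of
        the closed-form entropy rate of the chain."""
        lm = ToyLanguageModel.random(8, seed=2, concentration=0.7)
        n = 10_000
        stream = generate_word_stream(lm, n, seed=3)
        s = stream["surprisal"].to_numpy()[1:]  # drop the stationary start
        se = s.std() / np.sqrt(s.size)
        assert abs(s.mean() - lm.entropy_rate) < 3 * se

    def test_invalid_transition_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            ToyLanguageModel(["a", "b"], np.array([[0.5, 0.6], [0.5, 0.5]]))

    def test_reproducible(self):
        lm = ToyLanguageModel.random(5, seed=4)
        a = generate_word_stream(lm, 100, seed=9)
        b = generate_word_stream(lm, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCorrelatedFeatures:
    def test_target_correlation_frobenius(self):
        """Full 7-dimensional copula sample at n = 5000 lands within
        Frobenius distance 0.05 of the target correlation matrix."""
        df = correlated_word_features(5000, seed=1, sample_all=True)
        emp = np.corrcoef(df[list(FEATURE_ORDER)].to_numpy(), rowvar=False)
        dist = np.linalg.norm(emp - DEFAULT_FEATURE_CORRELATION)
        assert dist < 0.05

    def test_interaction_is_product_by_default(self):
        df = correlated_word_features(500, seed=2)
        assert np.allclose(df["interaction"], df["precision"] * df["surprisal"])

    def test_marginal_locations(self):
        df = correlated_word_features(20_000, seed=3)
        assert df["mean_f0"].mean() == pytest.approx(107.2, abs=1.5)
        assert df["mean_f0"].std() == pytest.approx(24.8, abs=1.5)
        assert df["voiced_duration"].mean() == pytest.approx(0.19, abs=0.02)

    def test_reproducible(self):
        a = correlated_word_features(300, seed=5)
        b = correlated_word_features(300, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestWordGains:
    def test_zero_betas_unit_gain(self):
        df = correlated_word_features(100, seed=1)
        assert np.allclose(word_gains(df, np.zeros(7)), 1.0)

    def test_gain_clipping_warns(self):
        df = correlated_word_features(200, seed=1)
        with pytest.warns(UserWarning, match="clipped"):
            g = word_gains(df, np.array([-2.0, 0, 0, 0, 0, 0, 0]))
        assert g.min() >= 0.1


class TestStimulusRoundTrip:
    def test_pitch_band_contains_f0_base(self, small_dataset):
        pitch = small_dataset.pitch_parts[0]
        band = pitch_band_from_percentiles(pitch)
        assert band.f_lo < 107.2 < band.f_hi

    def test_fundamental_waveform_recovers_word_f0(self, small_dataset):
        """Round trip: band-passing the synthetic audio and measuring
        per-word periodicity recovers the planted mean f0 within 2 Hz."""
        spec = small_dataset.spec
        audio, pitch, words = synthesize_stimulus(small_dataset.words, spec, seed=99)
        fs_audio = 8000.0
        band = pitch_band_from_percentiles(pitch)
        f1 = extract_fundamental_waveform(audio, fs_audio, band, fs_out=1000.0)
        checked = 0
        for _, w in words.iterrows():
            v0, v1 = w["voiced_intervals"][0]
            if v1 - v0 < 0.15:
                continue
            seg = f1[int(v0 * 1000) + 20 : int(v1 * 1000) - 20]
            # zero-crossing rate as an f0 estimate
            zc = np.sum(np.diff(np.signbit(seg)) != 0)
            f0_est = zc / 2 / (seg.size / 1000.0)
            assert abs(f0_est - w["mean_f0"]) < 2.0 + w["f0_rate"] * (v1 - v0) / 2
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5

    def test_envelope_modulation_periodicity(self, small_dataset):
        """f2 of the audio within a long word has its dominant
        periodicity at the planted f0 (autocorrelation oracle, +-2 ms)."""
        from f0track.stimulus import auditory_spectrogram, extract_hf_envelope_modulation

        spec = small_dataset.spec
        audio, pitch, words = synthesize_stimulus(small_dataset.words, spec, seed=99)
        band = pitch_band_from_percentiles(pitch)
        aspec = auditory_spectrogram(audio, 8000.0, n_channels=48, cf_range=(180, 3500))
        f2 = extract_hf_envelope_modulation(aspec, band)
        w = words.loc[words["voiced_duration"].idxmax()]
        v0, v1 = w["voiced_intervals"][0]
        seg = f2[int(v0 * 1000) + 10 : int(v1 * 1000) - 10]
        seg = seg - seg.mean()
        ac = np.correlate(seg, seg, mode="full")[seg.size - 1 :]
        lo = int(1000 / 180)  # shortest plausible period
        hi = int(1000 / 60)
        lag = lo + int(np.argmax(ac[lo : hi + 1]))
        period_planted = 1000.0 / w["mean_f0"]
        assert abs(lag - period_planted) <= 2.0


class TestSimulatedEEG:
    def test_bit_reproducible(self, small_dataset):
        spec = small_dataset.spec
        a = simulate_eeg(small_dataset.feature_parts[0], small_dataset.words_per_part[0], spec, 42)
        b = simulate_eeg(small_dataset.feature_parts[0], small_dataset.words_per_part[0], spec, 42)
        assert np.array_equal(a, b)

    def test_snr_scaling(self, small_dataset):
        spec_hi = SyntheticSpec(n_words=40, n_parts=1, n_subjects=1, seed=1, snr_db=20.0)
        spec_lo = SyntheticSpec(n_words=40, n_parts=1, n_subjects=1, seed=1, snr_db=-20.0)
        a = generate_dataset(spec_hi)
        b = generate_dataset(spec_lo)
        # identical seeds: same stimulus; low-SNR EEG has much larger variance
        assert b.eeg_parts_per_subject[0][0].std() > 5 * a.eeg_parts_per_subject[0][0].std()

    def test_dataset_reproducible(self):
        spec = SyntheticSpec(n_words=30, n_parts=2, n_subjects=2, seed=11)
        a = generate_dataset(spec)
        b = generate_dataset(spec)
        for p in range(2):
            assert np.array_equal(a.feature_parts[p].f1, b.feature_parts[p].f1)
            for s in range(2):
                assert np.array_equal(
                    a.eeg_parts_per_subject[s][p], b.eeg_parts_per_subject[s][p]
                )


def test_probability_source_round_trip():
    """Information features recomputed from the derived probability table
    reproduce the planted linguistic features exactly."""
    df = correlated_word_features(200, seed=8)
    src = probability_source_from_features(df)
    for pos in (0, 17, 199):
        inv_f, surp, prec, inter, _ = information_features(src, pos)
        assert inv_f == pytest.approx(df["inv_freq"].iloc[pos], rel=1e-12)
        assert surp == pytest.approx(df["surprisal"].iloc[pos], rel=1e-12)
        assert prec == pytest.approx(df["precision"].iloc[pos], rel=1e-9)
        assert inter == pytest.approx(df["interaction"].iloc[pos], rel=1e-9)


def test_planted_kernel_peaks_in_forward_grid():
    spec = SyntheticSpec()
    grid = LagGrid(-250.0, 499.0, 1000.0)
    for k in spec.kernels:
        assert grid.lag_min_ms < k.peak_ms < grid.lag_max_ms
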