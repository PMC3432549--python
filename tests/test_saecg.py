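"""Beat detection, the three alignment methods, averaging, wavelet denoising."""

import numpy as np
import pytest

from vlpdetect.errors import AlignmentError, BeatDetectionError, RecordError
from vlpdetect.record import EcgRecord
from vlpdetect.saecg import (
    BeatSet,
    align_double_level,
    align_normalized_integrals,
    align_woody,
    average_beats,
    detect_r_peaks,
    segment_beats,
    select_reference_lead,
    wavelet_denoise,
)
from vlpdetect.synth_ecg import generate_clean_ecg

FS = 1000.0


def _template_beat(width=700, seed=0):
    """One clean band-limited beat-like pulse centred in the window."""
    t = np.arange(width)
    x = 500 * np.exp(-((t - 300) ** 2) / (2 * 8.0**2))
    x -= 180 * np.exp(-((t - 318) ** 2) / (2 * 6.0**2))
    return x


def _beatset_from(beats_1d, pre=300, ref=0):
    arr = np.stack([b[:, None] for b in beats_1d])
    return BeatSet(beats=arr, r_indices=np.arange(len(beats_1d)) * 1000 + pre,
                   pre=pre, post=arr.shape[1] - pre, fs=FS, reference_lead=ref)


class TestDetectRPeaks:
    def test_peaks_match_generator_truth_within_5_ms(self):
        rec = generate_clean_ecg(10, seed=1)
        peaks = detect_r_peaks(rec)
        truth = np.asarray(rec.meta["r_peaks"])
        assert len(peaks) == 10
        assert np.all(np.abs(peaks - truth) <= 5)

    def test_flat_signal_raises(self):
        rec = EcgRecord(signal=np.zeros((5000, 1)), fs=FS)
        with pytest.raises(BeatDetectionError):
            detect_r_peaks(rec)

    def test_two_beats_give_exactly_two_peaks(self):
        rec = generate_clean_ecg(2, seed=2)
        assert len(detect_r_peaks(rec)) == 2


class TestSelectReferenceLead:
    def test_scaled_lead_wins(self):
        rec = generate_clean_ecg(5, seed=0, n_leads=4, lead_gains=np.array([0.5, 0.5, 1.0, 0.5]))
        peaks = detect_r_peaks(rec)
        assert select_reference_lead(rec, peaks) == 2

    def test_single_lead_returns_zero(self):
        rec = generate_clean_ecg(3, seed=0, n_leads=1, lead_gains=np.ones(1))
        assert select_reference_lead(rec, detect_r_peaks(rec)) == 0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        gains = rng.uniform(0.3, 1.0, size=5)
        rec = generate_clean_ecg(6, seed=0, n_leads=5, lead_gains=gains)
        peaks = detect_r_peaks(rec)
        expected = int(np.argmax(np.median(np.abs(rec.signal[peaks, :]), axis=0)))
        assert select_reference_lead(rec, peaks) == expected


class TestAlignWoody:
    def test_noiseless_shift_recovery_is_exact(self):
        base = _template_beat()
        lags = [0, -7, 12]
        beats = _beatset_from([np.roll(base, d) for d in lags])
        align_woody(beats, refine_iterations=0)
        assert list(beats.shifts) == lags

    def test_identical_beats_align_with_unit_correlation(self):
        base = _template_beat()
        beats = _beatset_from([base.copy() for _ in range(4)])
        align_woody(beats)
        assert np.all(beats.shifts == 0)
        np.testing.assert_allclose(beats.correlations, 1.0, atol=1e-12)

    def test_noisy_shift_recovery_within_2_samples(self):
        rng = np.random.default_rng(4)
        base = _template_beat()
        sig_rms = np.sqrt(np.mean(base**2))
        noise_rms = sig_rms / 10 ** (10 / 20)  # SNR 10 dB
        lags = [0, -9, 5, 14, -3, 7, 0, -12]
        beats = _beatset_from(
            [np.roll(base, d) + rng.normal(0, noise_rms, len(base)) for d in lags]
        )
        align_woody(beats, min_correlation=0.0)
        assert np.all(np.abs(beats.shifts - np.array(lags)) <= 2)

    def test_all_beats_rejected_raises(self):
        # degenerate zero template: correlation is defined as 0 for every
        # beat (including the template itself), so all beats fail the gate
        rng = np.random.default_rng(5)
        base = np.zeros(700)
        beats = _beatset_from([base] + [rng.normal(0, 500, 700) for _ in range(3)])
        with pytest.raises(AlignmentError):
            align_woody(beats, min_correlation=0.95)

    def test_equivariance_under_common_lag(self):
        base = _template_beat()
        lags = [0, -7, 12]
        b1 = _beatset_from([np.roll(base, d) for d in lags])
        b2 = _beatset_from([np.roll(base, d + 6) for d in lags])
        align_woody(b1, refine_iterations=0)
        align_woody(b2, refine_iterations=0)
        # common shift lands in the template; relative delays are preserved
        assert list(b2.shifts - b2.shifts[0]) == list(b1.shifts - b1.shifts[0])

    def test_agrees_with_matched_filter_formulation(self):
        """Peak of normalized xcorr = peak of convolution with reversed template."""
        rng = np.random.default_rng(6)
        base = _template_beat()
        beat = np.roll(base, 9) + rng.normal(0, 5, len(base))
        beats = _beatset_from([base, beat])
        align_woody(beats, min_correlation=0.0, refine_iterations=0)
        conv = np.convolve(beat, base[::-1], mode="full")
        lag_mf = np.argmax(conv) - (len(base) - 1)
        assert beats.shifts[1] == lag_mf


class TestAlignDoubleLevel:
    def test_symmetric_triangle_fiducial_at_apex(self):
        tri = np.concatenate([np.linspace(0, 100, 51), np.linspace(100, 0, 51)[1:]])
        beat = np.zeros(700)
        beat[250:351] = tri
        beats = _beatset_from([beat, np.roll(beat, 17)])
        align_double_level(beats, threshold=50.0)
        assert list(beats.shifts) == [0, 17]

    def test_threshold_above_signal_raises(self):
        beats = _beatset_from([_template_beat()])
        with pytest.raises(AlignmentError):
            align_double_level(beats, threshold=1e6)


class TestAlignNormalizedIntegrals:
    def test_scaled_delayed_copy_recovers_delay(self):
        base = _template_beat()
        beats = _beatset_from([base, 2.5 * np.roll(base, 9)])
        align_normalized_integrals(beats)
        assert beats.shifts[1] == 9

    def test_zero_delay_recovered(self):
        base = _template_beat()
        beats = _beatset_from([base, base * 0.7])
        align_normalized_integrals(beats)
        assert beats.shifts[1] == 0

    def test_noisy_delay_within_2_samples_at_20_db(self):
        rng = np.random.default_rng(7)
        base = _template_beat()
        noise_rms = np.sqrt(np.mean(base**2)) / 10
        lags = [0, 6, -8, 11]
        beats = _beatset_from(
            [np.roll(base, d) + rng.normal(0, noise_rms, len(base)) for d in lags]
        )
        align_normalized_integrals(beats)
        assert np.all(np.abs(beats.shifts - np.array(lags)) <= 2)


class TestAverageBeats:
    def test_noise_reduced_to_about_one_tenth_at_n_100(self):
        rng = np.random.default_rng(8)
        base = _template_beat()
        beats = _beatset_from([base + rng.normal(0, 10.0, len(base)) for _ in range(100)])
        avg = average_beats(beats)
        assert avg.n_beats_used == 100
        assert abs(avg.residual_noise_sigma - 1.0) / 1.0 < 0.3

    def test_single_beat_is_identity(self):
        base = _template_beat()
        beats = _beatset_from([base])
        avg = average_beats(beats, min_beats=1)
        np.testing.assert_allclose(avg.signal[:, 0], base)

    def test_deterministic_component_preserved(self):
        base = _template_beat()
        beats = _beatset_from([base.copy() for _ in range(20)])
        avg = average_beats(beats)
        np.testing.assert_allclose(avg.signal[:, 0], base, atol=1e-10)

    def test_noise_follows_inverse_sqrt_n(self):
        rng = np.random.default_rng(9)
        base = _template_beat()
        sigmas = {}
        for n in (4, 16, 64, 256):
            reps = []
            for _ in range(6):
                beats = _beatset_from([base + rng.normal(0, 10.0, len(base)) for _ in range(n)])
                reps.append(average_beats(beats).residual_noise_sigma)
            sigmas[n] = np.mean(reps)
        for n, s in sigmas.items():
            assert abs(s - 10.0 / np.sqrt(n)) / (10.0 / np.sqrt(n)) < 0.2

    def test_too_few_beats_raises(self):
        beats = _beatset_from([_template_beat()])
        with pytest.raises(AlignmentError):
            average_beats(beats, min_beats=5)


class TestWaveletDenoise:
    def test_zero_input_zero_output(self):
        out = wavelet_denoise(np.zeros(512))
        assert np.allclose(out, 0.0)

    def test_pure_noise_strongly_suppressed(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 10.0, 1024)
        out = wavelet_denoise(x)
        assert np.sqrt(np.mean(out**2)) < 0.3 * np.sqrt(np.mean(x**2))

    def test_snr_improves_by_at_least_5_db(self):
        rng = np.random.default_rng(11)
        clean = _template_beat()
        noise_rms = np.sqrt(np.mean(clean**2)) / 10 ** (10 / 20)
        noisy = clean + rng.normal(0, noise_rms, len(clean))
        den = wavelet_denoise(noisy)

        def snr(y):
            return 10 * np.log10(np.sum(clean**2) / np.sum((y - clean) ** 2))

        assert snr(den) >= snr(noisy) + 5.0

    def test_zero_threshold_is_perfect_reconstruction(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=777)
        np.testing.assert_allclose(wavelet_denoise(x, threshold_scale=0.0), x, atol=1e-10)

    def test_too_short_signal_raises(self):
        with pytest.raises(RecordError):
            wavelet_denoise(np.zeros(16), levels=5)


def test_segment_beats_skips_transient_and_bounds():
    rec = generate_clean_ecg(6, seed=0)
    rec.meta["transient_samples"] = 600
    peaks = detect_r_peaks(rec)
    beats = segment_beats(rec, peaks)
    # first truth R is at 800; its window starts at 500 < 600 -> dropped
    assert beats.n_beats == 5
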