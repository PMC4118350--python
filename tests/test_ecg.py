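"""ECG preprocessing, adaptive-threshold R detection, wave location."""

import numpy as np
import pytest

from caretrace.ecg import (
    BeatAnnotation,
    DetectorParams,
    EcgSignal,
    beat_features,
    detect_r_peaks,
    locate_waves,
    preprocess,
    update_threshold,
)
from caretrace.simulate import EcgScript, simulate_ecg


def match_counts(detected, truth, tol_samples):
    """(true positives, false positives, false negatives) by nearest match."""
    truth = np.asarray(truth)
    tp = sum(1 for d in detected if truth.size and np.min(np.abs(truth - d)) <= tol_samples)
    fn = sum(1 for t in truth if len(detected) == 0 or np.min(np.abs(np.asarray(detected) - t)) > tol_samples)
    return tp, len(detected) - tp, fn


@pytest.fixture(scope="module")
def clean_60bpm():
    return simulate_ecg(EcgScript(duration_s=10.0, base_rate_bpm=60.0, seed=11))


class TestPreprocess:
    def test_zero_signal_stays_zero(self):
        sig = EcgSignal(rate=256.0, samples=np.zeros(1024))
        assert np.allclose(preprocess(sig), 0.0)

    def test_dc_offset_removed(self):
        sig = EcgSignal(rate=256.0, samples=np.full(1024, 0.7))
        assert np.max(np.abs(preprocess(sig))) < 1e-6

    def test_envelope_maxima_align_with_true_r(self, clean_60bpm):
        """The 10 dominant envelope peaks sit within 50 ms of the 10 true
        R positions (generator ground truth as oracle)."""
        from scipy.signal import find_peaks

        sig, truth = clean_60bpm
        env = preprocess(sig)
        peaks, _ = find_peaks(env, distance=int(0.4 * sig.rate))
        top = peaks[np.argsort(env[peaks])[-len(truth):]]
        tol = int(0.05 * sig.rate)
        true_r = np.array([b.r for b in truth])
        assert all(np.min(np.abs(true_r - p)) <= tol for p in top)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            preprocess(EcgSignal(rate=256.0, samples=np.zeros(10)))


class TestUpdateThreshold:
    @pytest.mark.parametrize(
        "tr, alpha, gamma, peak, expected",
        [(0.0, 1.0, 1.0, 5.0, 5.0), (7.0, 0.0, 1.0, 100.0, 7.0),
         (10.0, 0.5, 0.5, 100.0, 30.0)],
    )
    def test_recurrence(self, tr, alpha, gamma, peak, expected):
        assert update_threshold(tr, peak, alpha, gamma) == pytest.approx(expected)


class TestDetectRPeaks:
    def test_flat_signal_gives_no_peaks(self):
        sig = EcgSignal(rate=256.0, samples=np.zeros(2560))
        assert len(detect_r_peaks(preprocess(sig), sig)) == 0

    def test_clean_60bpm_finds_every_beat_within_20ms(self, clean_60bpm):
        sig, truth = clean_60bpm
        r = detect_r_peaks(preprocess(sig), sig)
        assert len(r) == len(truth) == 10
        tol = int(round(0.020 * sig.rate))
        tp, fp, fn = match_counts(r, [b.r for b in truth], tol)
        assert fp == 0 and fn == 0

    def test_amplitude_scaling_leaves_count_unchanged(self, clean_60bpm):
        sig, _ = clean_60bpm
        base = detect_r_peaks(preprocess(sig), sig)
        for scale in (0.5, 2.0, 10.0):
            scaled = EcgSignal(rate=sig.rate, samples=sig.samples * scale)
            got = detect_r_peaks(preprocess(scaled), scaled)
            assert len(got) == len(base)

    def test_noisy_recall_precision(self):
        """At roughly 14 dB SNR, recall and precision stay above 0.95."""
        sig, truth = simulate_ecg(
            EcgScript(duration_s=60.0, seed=3, noise_sd_mv=0.03,
                      rr_jitter_fraction=0.03)
        )
        r = detect_r_peaks(preprocess(sig), sig)
        tol = int(round(0.020 * sig.rate))
        tp, fp, fn = match_counts(r, [b.r for b in truth], tol)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestLocateWaves:
    def test_waves_recovered_within_30ms(self, clean_60bpm):
        sig, truth = clean_60bpm
        r = detect_r_peaks(preprocess(sig), sig)
        beats = locate_waves(sig, r)
        assert len(beats) == len(truth)
        tol = 0.030 * sig.rate
        for got, want in zip(beats, truth):
            for wave in ("p", "q", "r", "s", "t"):
                g, w = getattr(got, wave), getattr(want, wave)
                assert g is not None and w is not None
                assert abs(g - w) <= tol, wave

    def test_ordering_invariant(self, clean_60bpm):
        sig, _ = clean_60bpm
        beats = locate_waves(sig, detect_r_peaks(preprocess(sig), sig))
        for b in beats:
            present = [i for i in (b.p, b.q, b.r, b.s, b.t) if i is not None]
            assert present == sorted(present)

    def test_missing_p_marked_absent(self):
        script = EcgScript(duration_s=10.0, seed=5, p_wave=(0.0, 25.0, -160.0))
        sig, _ = simulate_ecg(script)
        beats = locate_waves(sig, detect_r_peaks(preprocess(sig), sig))
        assert beats and all(b.p is None for b in beats)

    def test_q_s_are_window_minima(self, clean_60bpm):
        """Brute-force oracle: Q/S equal the argmin over the search window."""
        sig, _ = clean_60bpm
        params = DetectorParams()
        half = int(round(params.qs_half_window_ms / 1000 * sig.rate))
        beats = locate_waves(sig, detect_r_peaks(preprocess(sig), sig), params)
        x = sig.samples
        for b in beats:
            assert x[b.q] == np.min(x[b.r - half:b.r])
            assert x[b.s] == np.min(x[b.r + 1:b.r + half + 1])

    def test_truncated_edge_beats_dropped(self):
        sig = EcgSignal(rate=256.0, samples=np.random.default_rng(0).normal(size=512))
        assert locate_waves(sig, [2, 509]) == []


class TestBeatFeatures:
    def test_inter_beat_r_interval(self):
        beats = [BeatAnnotation(r=256, q=250, s=262),
                 BeatAnnotation(r=461, q=455, s=467)]
        feats = beat_features(beats, 256.0)
        assert feats[0].ri is None
        assert feats[1].ri == pytest.approx((461 - 256) * 1000.0 / 256.0)

    def test_first_beat_has_no_inter_beat_fields(self):
        feats = beat_features([BeatAnnotation(r=256, q=250, s=262)], 256.0)
        f = feats[0]
        assert f.pi is f.qi is f.ri is f.si is f.ti is None

    def test_intra_beat_distance_conversion(self):
        feats = beat_features([BeatAnnotation(r=256, q=250, s=262)], 256.0)
        assert feats[0].dqr == pytest.approx(6 / 256 * 1000.0)  # ~23.4 ms
        assert feats[0].drs == pytest.approx(6 / 256 * 1000.0)
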