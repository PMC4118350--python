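"""Fingerprint calibration and the significance-product locator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import t as t_dist

from caretrace.rssi import (
    CalibrationConfig,
    Fingerprint,
    LocationEstimate,
    RssiScan,
    TrackState,
    alpha_level,
    calibrate,
    filter_outliers,
    fingerprint_probabilities,
    locate,
    standardize_residual,
    update_track,
)

finite_rssi = st.floats(min_value=-100.0, max_value=-20.0)


class TestFilterOutliers:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([-60.0, -60.0, -60.0, -60.0], [-60.0, -60.0, -60.0, -60.0]),
            ([-50.0, -51.0, -49.0, -50.0, -90.0], [-50.0, -51.0, -49.0, -50.0]),
            ([-40.0, -42.0, -44.0, -46.0, -48.0, -100.0],
             [-40.0, -42.0, -44.0, -46.0, -48.0]),
        ],
    )
    def test_fences(self, values, expected):
        """3x-IQR fences drop far readings; identical values survive via the
        median fallback; order is preserved."""
        assert filter_outliers(values) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers([])

    @given(st.lists(finite_rssi, min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving_subset_keeping_median(self, values):
        """The filter returns a non-empty, order-preserving subsequence and
        never discards values equal to the median (a single fence pass is
        not idempotent in general: removal tightens the quartiles)."""
        once = filter_outliers(values)
        assert once
        it = iter(values)
        assert all(any(v == w for w in it) for v in once)  # subsequence
        med = np.median(values)
        assert (med in values) <= (med in once or len(once) < len(values))

    @given(st.lists(finite_rssi, min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_repeated_application_reaches_fixpoint(self, values):
        """Iterating the filter strictly shrinks the set until it stabilizes."""
        current = list(values)
        for _ in range(len(values) + 1):
            nxt = filter_outliers(current)
            if nxt == current:
                break
            assert len(nxt) < len(current)
            current = nxt
        else:
            pytest.fail("filter did not converge")
        assert filter_outliers(current) == current


class TestCalibrate:
    def test_constant_readings_hit_sd_floor(self):
        fp = Fingerprint(
            id="a",
            scans=[RssiScan(readings={"x": -60.0}) for _ in range(5)],
        )
        model = calibrate([fp])
        st_ = model.stats["a"]["x"]
        assert st_.mean == -60.0
        assert st_.sd == model.config.sd_floor

    def test_unobserved_bssid_imputed_at_floor(self, toy_fingerprints):
        """A BSSID seen only in one fingerprint gets the global floor
        elsewhere: most negative observed RSSI pushed 20% farther from 0."""
        extra = Fingerprint(
            id="room_c",
            scans=[
                RssiScan(readings={"ap00": -90.0, "ap99": -50.0}),
                RssiScan(readings={"ap00": -88.0, "ap99": -52.0}),
            ],
        )
        model = calibrate(list(toy_fingerprints) + [extra])
        assert model.floor == pytest.approx(-90.0 * 1.2)
        st_a = model.stats["room_a"]["ap99"]
        assert st_a.imputed
        assert st_a.mean == pytest.approx(-108.0)
        assert st_a.n == model.config.pseudo_count

    def test_statistics_computed_on_filtered_readings(self):
        readings = [-50.0, -51.0, -49.0, -50.0, -90.0]
        fp = Fingerprint(
            id="a", scans=[RssiScan(readings={"x": r}) for r in readings]
        )
        model = calibrate([fp])
        kept = filter_outliers(readings)
        st_ = model.stats["a"]["x"]
        assert st_.mean == pytest.approx(np.mean(kept))
        assert st_.sd == pytest.approx(max(np.std(kept, ddof=1), 0.5))
        assert st_.n == len(kept)

    def test_single_scan_fingerprint_rejected(self):
        with pytest.raises(ValueError):
            Fingerprint(id="a", scans=[RssiScan(readings={"x": -60.0})])


class TestStandardizeResidual:
    @pytest.mark.parametrize(
        "r, mean, sd, n, expected",
        [(-60.0, -60.0, 5.0, 25, 0.0), (-55.0, -60.0, 5.0, 25, 5.0),
         (-65.0, -60.0, 5.0, 1, -1.0)],
    )
    def test_standard_error_scale(self, r, mean, sd, n, expected):
        assert standardize_residual(r, mean, sd, n) == pytest.approx(expected)

    def test_standard_deviation_scale(self):
        assert standardize_residual(
            -55.0, -60.0, 5.0, 25, scale="standard_deviation"
        ) == pytest.approx(1.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize_residual(-55.0, -60.0, 0.0, 25)


class TestAlphaLevel:
    def test_zero_statistic_gives_one(self):
        assert alpha_level(0.0, 10) == 1.0

    def test_small_sample_matches_numeric_t_tail(self):
        """Independent oracle: numerically integrate the t pdf on df = 9."""
        df = 9
        tail, _ = quad(lambda u: t_dist.pdf(u, df), 2.0, np.inf)
        assert alpha_level(2.0, 10) == pytest.approx(2.0 * tail, rel=1e-8)
        assert alpha_level(2.0, 10) == pytest.approx(0.0766, abs=5e-4)

    def test_large_sample_uses_normal_tail(self):
        assert alpha_level(1.96, 1000) == pytest.approx(0.05, abs=5e-4)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            alpha_level(1.0, 1)

    def test_clamped_below(self):
        assert alpha_level(1e6, 10) >= 1e-300


class TestFingerprintProbabilities:
    def test_single_fingerprint_gets_probability_one(self):
        fp = Fingerprint(
            id="only",
            scans=[RssiScan(readings={"x": -60.0 + d}) for d in (-1, 0, 1)],
        )
        model = calibrate([fp])
        est = fingerprint_probabilities(RssiScan(readings={"x": -58.0}), model)
        assert est.probabilities["only"] == pytest.approx(1.0)

    def test_mirror_symmetric_scan_splits_evenly(self, toy_model):
        est = fingerprint_probabilities(
            RssiScan(readings={"ap00": -55.0, "ap01": -55.0}), toy_model
        )
        assert est.probabilities["room_a"] == pytest.approx(0.5, abs=1e-9)
        assert est.probabilities["room_b"] == pytest.approx(0.5, abs=1e-9)

    def test_log_domain_matches_direct_product(self, toy_model):
        """Brute-force oracle: multiply the alphas directly, no logs."""
        scan = RssiScan(readings={"ap00": -45.0, "ap01": -65.0})
        est = fingerprint_probabilities(scan, toy_model)
        direct = {}
        for fid in toy_model.fingerprint_ids:
            prod = 1.0
            for bssid in sorted(toy_model.bssids):
                s = toy_model.stats[fid][bssid]
                t = standardize_residual(scan.readings[bssid], s.mean, s.sd, s.n)
                prod *= alpha_level(t, s.n)
            direct[fid] = prod
        total = sum(direct.values())
        for fid in direct:
            assert est.probabilities[fid] == pytest.approx(
                direct[fid] / total, abs=1e-12
            )

    def test_probabilities_normalize_and_ignore_bssid_order(self, toy_model):
        a = RssiScan(readings={"ap00": -42.0, "ap01": -68.0})
        b = RssiScan(readings={"ap01": -68.0, "ap00": -42.0})
        ea = fingerprint_probabilities(a, toy_model)
        eb = fingerprint_probabilities(b, toy_model)
        assert sum(ea.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        assert ea.probabilities == eb.probabilities
        assert min(ea.probabilities.values()) >= 0.0

    def test_scan_at_fingerprint_means_wins(self, toy_model):
        est = fingerprint_probabilities(
            RssiScan(readings={"ap00": -40.0, "ap01": -70.0}), toy_model
        )
        assert est.winner == "room_a"

    def test_disjoint_scan_rejected(self, toy_model):
        with pytest.raises(ValueError):
            fingerprint_probabilities(RssiScan(readings={"zz": -50.0}), toy_model)


def _est(winner):
    return LocationEstimate(probabilities={winner: 1.0}, winner=winner)


class TestUpdateTrack:
    def test_k1_commits_immediately(self):
        state = TrackState(k=1)
        state = update_track(_est("a"), state)
        assert state.committed == "a"

    def test_commits_after_k_consecutive_wins(self):
        """Winner sequence A,A,B,B,B with k=3 commits B at the fifth step."""
        state = TrackState(k=3)
        committed = []
        for w in ["a", "a", "b", "b", "b"]:
            state = update_track(_est(w), state)
            committed.append(state.committed)
        assert committed == [None, None, None, None, "b"]

    def test_alternating_never_commits(self):
        state = TrackState(k=2)
        for w in ["a", "b", "a", "b", "a", "b"]:
            state = update_track(_est(w), state)
        assert state.committed is None

    def test_counter_never_exceeds_k(self):
        state = TrackState(k=2)
        for _ in range(10):
            state = update_track(_est("a"), state)
            assert state.count <= state.k


class TestLocate:
    def test_noisy_scan_near_second_fingerprint_wins(self, toy_model):
        est, _ = locate(
            RssiScan(readings={"ap00": -69.0, "ap01": -41.0}),
            toy_model,
            TrackState(k=1),
        )
        assert est.winner == "room_b"

    def test_parameter_recovery_on_synthetic_environment(self, synthetic_rssi):
        """At 2 dBm shadowing noise with 3 APs, at least 95% of held-out
        scans land on their true fingerprint."""
        fingerprints, test = synthetic_rssi
        model = calibrate(fingerprints)
        hits = sum(
            1
            for label, scan in test
            if fingerprint_probabilities(scan, model).winner == label
        )
        assert hits / len(test) >= 0.95
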