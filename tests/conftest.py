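import pytest

from caretrace.rssi import CalibrationConfig, Fingerprint, RssiScan, calibrate
from caretrace.simulate import default_environment, simulate_rssi


@pytest.fixture(scope="session")
def toy_fingerprints():
    """Two well-separated fingerprints over two BSSIDs, four scans each."""

    def scans(means, deltas=(-1.0, 0.0, 0.0, 1.0)):
        return [
            RssiScan(readings={b: m + d for b, m in means.items()}, timestamp=float(j))
            for j, d in enumerate(deltas)
        ]

    return [
        Fingerprint(id="room_a", scans=scans({"ap00": -40.0, "ap01": -70.0})),
        Fingerprint(id="room_b", scans=scans({"ap00": -70.0, "ap01": -40.0})),
    ]


@pytest.fixture(scope="session")
def toy_model(toy_fingerprints):
    return calibrate(toy_fingerprints, CalibrationConfig())


@pytest.fixture(scope="session")
def synthetic_environment():
    return default_environment(noise_sd=2.0)


@pytest.fixture(scope="session")
def synthetic_rssi(synthetic_environment):
    """Calibration set and labeled held-out scans at the study conditions."""
    return simulate_rssi(
        synthetic_environment, scans_per_fingerprint=50,
        test_scans_per_fingerprint=50, seed=20140605,
    )
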