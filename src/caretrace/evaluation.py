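"""Evaluation harness: repeated-holdout counts and baseline classifiers.

Mirrors the original evaluation design for the localization system: two
independently collected calibration sets A and B per repetition; each
method is trained on one and scored on the other in both directions,
producing per-repetition correct-classification counts.  The proposal
(significance-level-product locator, without the time-series stabilizer)
is compared against a naive-Bayes classifier over discretized RSSI and an
RBF SVM, and count rows are compared pairwise with the Mann-Whitney U
test (normal approximation with midrank ties and continuity correction).

The published correct-classification counts ship as a packaged fixture
(``load_reference_counts``) so the statistical comparison can be rerun on
the original numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.naive_bayes import CategoricalNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .rssi import (
    CalibrationConfig,
    Fingerprint,
    RssiScan,
    calibrate,
    fingerprint_probabilities,
)
from .simulate import RssiEnvironment, simulate_rssi

__all__ = [
    "BaselineConfig",
    "train_baseline",
    "proposal_classifier",
    "evaluate_holdout",
    "mann_whitney",
    "load_reference_counts",
    "benchmark",
    "pairwise_pvalues",
]


@dataclass(frozen=True)
class BaselineConfig:
    bin_width_dbm: float = 5.0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"


def _universe(fingerprints: Sequence[Fingerprint]) -> list[str]:
    out: set[str] = set()
    for fp in fingerprints:
        out |= fp.bssids()
    return sorted(out)


def _floor(fingerprints: Sequence[Fingerprint], factor: float = 1.2) -> float:
    vals = [
        r for fp in fingerprints for scan in fp.scans for r in scan.readings.values()
    ]
    return min(vals) * factor


def _matrix(
    scans: Sequence[RssiScan], universe: Sequence[str], floor: float
) -> np.ndarray:
    rows = [[scan.readings.get(b, floor) for b in universe] for scan in scans]
    return np.asarray(rows, float)


class _SklearnClassifier:
    """Wraps an sklearn estimator with the BSSID universe and imputation."""

    def __init__(self, est, universe, floor, binner=None):
        self._est = est
        self._universe = list(universe)
        self._floor = floor
        self._binner = binner

    def predict(self, scan: RssiScan) -> str:
        x = _matrix([scan], self._universe, self._floor)
        if self._binner is not None:
            x = self._binner(x)
        return str(self._est.predict(x)[0])


def train_baseline(
    method: str,
    fingerprints: Sequence[Fingerprint],
    config: BaselineConfig | None = None,
):
    """Fit a baseline classifier ('bayes' or 'svm') on calibration scans.

    bayes: naive Bayes over RSSI discretized into fixed-width bins
    (5 dBm by default) with Laplace smoothing; svm: RBF-kernel multiclass
    SVM on standardized features.  Unseen BSSIDs in a live scan are filled
    with the imputation floor before prediction.
    """
    config = config or BaselineConfig()
    if len(fingerprints) < 2:
        raise ValueError("need at least two fingerprints (classes)")
    universe = _universe(fingerprints)
    floor = _floor(fingerprints)
    x_rows, y = [], []
    for fp in fingerprints:
        for scan in fp.scans:
            x_rows.append([scan.readings.get(b, floor) for b in universe])
            y.append(fp.id)
    x = np.asarray(x_rows, float)

    if method == "bayes":
        # bins anchored at the floor so any live reading maps to a valid bin
        def binner(a: np.ndarray) -> np.ndarray:
            b = np.floor((a - floor) / config.bin_width_dbm).astype(int)
            return np.clip(b, 0, 63)

        est = CategoricalNB(alpha=1.0, min_categories=64)
        est.fit(binner(x), y)
        return _SklearnClassifier(est, universe, floor, binner)
    if method == "svm":
        est = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma)
        )
        est.fit(x, y)
        return _SklearnClassifier(est, universe, floor)
    raise ValueError(f"unknown baseline {method!r}")


def proposal_classifier(
    fingerprints: Sequence[Fingerprint], config: CalibrationConfig | None = None
):
    """The probabilistic locator as a plain classifier (no time series)."""
    model = calibrate(fingerprints, config)

    class _Proposal:
        def predict(self, scan: RssiScan) -> str:
            return fingerprint_probabilities(scan, model).winner

    return _Proposal()


def evaluate_holdout(
    classifier, labeled_scans: Sequence[tuple[str, RssiScan]]
) -> int:
    """Count of held-out scans whose prediction matches the true label."""
    return sum(
        1 for label, scan in labeled_scans if classifier.predict(scan) == label
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Default is the normal approximation with midrank tie correction and
    continuity correction; ``exact=True`` switches to the exact permutation
    null (no tie handling beyond midranks, small samples only).
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def load_reference_counts() -> pd.DataFrame:
    """The published per-repetition correct-classification counts.

    Rows: Proposal, Bayesian, SVM; columns a1..b5 are the two holdout
    directions of the five repetitions.
    """
    ref = importlib.resources.files("caretrace").joinpath(
        "data/classification_counts.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def benchmark(
    env: RssiEnvironment,
    reps: int = 5,
    scans_per_fingerprint: int = 50,
    seed: int = 0,
    methods: Sequence[str] = ("proposal", "bayes", "svm"),
) -> pd.DataFrame:
    """Repeated-holdout counts on a synthetic environment.

    For each repetition two independent calibration sets are drawn; each
    method is trained on one and scored on the other, in both directions
    (columns ``a<r>`` and ``b<r>``), plus a trailing ``average`` column.
    """
    rng = np.random.default_rng(seed)
    rows: dict[str, list[int]] = {m: [] for m in methods}
    cols: list[str] = []
    for r in range(1, reps + 1):
        seed_a = int(rng.integers(0, 2**31 - 1))
        seed_b = int(rng.integers(0, 2**31 - 1))
        set_a, _ = simulate_rssi(env, scans_per_fingerprint, 0, seed=seed_a)
        set_b, _ = simulate_rssi(env, scans_per_fingerprint, 0, seed=seed_b)
        flat_a = [(fp.id, s) for fp in set_a for s in fp.scans]
        flat_b = [(fp.id, s) for fp in set_b for s in fp.scans]
        cols += [f"a{r}", f"b{r}"]
        for m in methods:
            clf_a = (
                proposal_classifier(set_a)
                if m == "proposal"
                else train_baseline(m, set_a)
            )
            clf_b = (
                proposal_classifier(set_b)
                if m == "proposal"
                else train_baseline(m, set_b)
            )
            # a_r: model from A scores B's scans; b_r: the converse
            rows[m].append(evaluate_holdout(clf_a, flat_b))
            rows[m].append(evaluate_holdout(clf_b, flat_a))
    df = pd.DataFrame(rows, index=cols).T
    df["average"] = df.mean(axis=1)
    return df


def pairwise_pvalues(counts: pd.DataFrame, exact: bool = False) -> pd.DataFrame:
    """Symmetric matrix of two-sided Mann-Whitney p-values between rows."""
    data = counts.drop(columns=["average"], errors="ignore")
    names = list(data.index)
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                _, p = mann_whitney(data.loc[a].values, data.loc[b].values, exact)
                out.loc[a, b] = out.loc[b, a] = p
    return out
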