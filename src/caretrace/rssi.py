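"""Probabilistic WiFi fingerprint localization.

Room-level indoor positioning from received signal strength (RSSI).  A
calibration phase records repeated WiFi scans at known positions
("fingerprints"); at run time a live scan is assigned to the fingerprint
whose calibrated per-access-point RSSI distributions it matches best.

The match score for fingerprint *i* is the product over access points
(BSSIDs) *s* of two-sided significance levels ``alpha_{i,s}``: each live
reading is standardized against the fingerprint's calibrated mean and
spread, and the tail probability of the resulting t-statistic becomes the
per-BSSID factor.  Products are normalized across fingerprints to yield a
probability vector, and a consecutive-win time series stabilizes the
committed position against transient signal fluctuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "RssiScan",
    "Fingerprint",
    "CalibrationConfig",
    "CalibrationModel",
    "LocationEstimate",
    "TrackState",
    "filter_outliers",
    "calibrate",
    "standardize_residual",
    "alpha_level",
    "fingerprint_probabilities",
    "update_track",
    "locate",
]


@dataclass(frozen=True)
class RssiScan:
    """One WiFi scan: BSSID -> RSSI (dBm), optionally timestamped."""

    readings: Mapping[str, float]
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.readings:
            raise ValueError("scan has no readings")
        for bssid, rssi in self.readings.items():
            if not math.isfinite(rssi):
                raise ValueError(f"non-finite RSSI {rssi!r} for BSSID {bssid!r}")


@dataclass(frozen=True)
class Fingerprint:
    """A calibration position with its repeated scans."""

    id: str
    scans: Sequence[RssiScan]

    def __post_init__(self) -> None:
        if len(self.scans) < 2:
            raise ValueError(
                f"fingerprint {self.id!r} has {len(self.scans)} scan(s); "
                "at least 2 are required to estimate a spread"
            )

    def bssids(self) -> set[str]:
        out: set[str] = set()
        for scan in self.scans:
            out.update(scan.readings)
        return out


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunables for calibration and matching.

    sd_floor
        Lower bound on the per-(fingerprint, BSSID) standard deviation in
        dBm; prevents zero-variance entries from collapsing the t-statistic.
    floor_factor
        Unobserved BSSIDs are imputed at (most negative observed RSSI)
        scaled by this factor, i.e. 20% farther from zero by default.
    pseudo_count
        Effective sample size assigned to imputed entries.
    residual_scale
        'standard_error' divides the residual by sd/sqrt(n) (the literal
        calibration formula); 'standard_deviation' divides by sd alone.
    alpha_eps
        Lower clamp on each significance level before log accumulation.
    normal_cutoff
        Sample sizes above this use the normal instead of Student-t tail.
    """

    sd_floor: float = 0.5
    floor_factor: float = 1.2
    pseudo_count: int = 2
    residual_scale: str = "standard_error"
    alpha_eps: float = 1e-300
    normal_cutoff: int = 30
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        if self.residual_scale not in ("standard_error", "standard_deviation"):
            raise ValueError(f"unknown residual_scale {self.residual_scale!r}")


@dataclass(frozen=True)
class BssidStats:
    mean: float
    sd: float
    n: int
    imputed: bool = False


@dataclass(frozen=True)
class CalibrationModel:
    """Per-(fingerprint, BSSID) robust statistics plus the imputation floor."""

    stats: Mapping[str, Mapping[str, BssidStats]]  # fingerprint id -> bssid -> stats
    bssids: frozenset[str]
    floor: float
    config: CalibrationConfig

    @property
    def fingerprint_ids(self) -> list[str]:
        return sorted(self.stats)


@dataclass(frozen=True)
class LocationEstimate:
    probabilities: Mapping[str, float]
    winner: str
    alphas: Optional[Mapping[str, Mapping[str, float]]] = None


@dataclass(frozen=True)
class TrackState:
    """Consecutive-win stabilizer for the committed position."""

    k: int = 3
    committed: Optional[str] = None
    candidate: Optional[str] = None
    count: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def filter_outliers(values: Iterable[float]) -> list[float]:
    """Remove RSSI outliers with 3x-IQR fences (strict), preserving order.

    Quartiles use linear interpolation between order statistics.  If the
    fences exclude everything (e.g. all values identical, IQR = 0), values
    equal to the median are retained instead.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no values to filter")
    if any(not math.isfinite(v) for v in vals):
        raise ValueError("non-finite RSSI value")
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    kept = [v for v in vals if lo < v < hi]
    if not kept:
        med = float(np.median(vals))
        kept = [v for v in vals if v == med]
    return kept


def calibrate(
    fingerprints: Sequence[Fingerprint],
    config: CalibrationConfig | None = None,
) -> CalibrationModel:
    """Build the calibration model from repeated scans per fingerprint.

    Per (fingerprint, BSSID), readings are outlier-filtered and summarized
    as mean, standard deviation (floored at ``sd_floor``) and retained
    count.  BSSIDs never seen in a fingerprint are imputed at the global
    floor — the most negative observed RSSI pushed 20% farther from zero —
    so every fingerprint covers the same BSSID universe.
    """
    config = config or CalibrationConfig()
    if not fingerprints:
        raise ValueError("no fingerprints")
    ids = [fp.id for fp in fingerprints]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fingerprint ids")

    universe: set[str] = set()
    all_rssi: list[float] = []
    for fp in fingerprints:
        universe |= fp.bssids()
        for scan in fp.scans:
            all_rssi.extend(scan.readings.values())
    if not universe:
        raise ValueError("no BSSIDs observed in any fingerprint")

    floor = min(all_rssi) * config.floor_factor
    if min(all_rssi) >= 0:  # dBm readings are negative in practice
        floor = min(all_rssi) - abs(min(all_rssi)) * (config.floor_factor - 1) - 1.0

    model_stats: dict[str, dict[str, BssidStats]] = {}
    for fp in fingerprints:
        per_bssid: dict[str, BssidStats] = {}
        for bssid in universe:
            readings = [
                scan.readings[bssid] for scan in fp.scans if bssid in scan.readings
            ]
            if not readings:
                per_bssid[bssid] = BssidStats(
                    mean=floor, sd=config.sd_floor, n=config.pseudo_count, imputed=True
                )
                continue
            kept = filter_outliers(readings)
            mean = float(np.mean(kept))
            sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
            sd = max(sd, config.sd_floor)
            per_bssid[bssid] = BssidStats(mean=mean, sd=sd, n=len(kept))
        model_stats[fp.id] = per_bssid

    return CalibrationModel(
        stats=model_stats, bssids=frozenset(universe), floor=floor, config=config
    )


def standardize_residual(
    r: float, mean: float, sd: float, n: int, scale: str = "standard_error"
) -> float:
    """Standardize a live reading against calibrated statistics.

    The default divides by sd/sqrt(n), mirroring the calibration-phase
    standardization; 'standard_deviation' divides by sd alone (treating the
    live reading as a single draw rather than a sample mean).
    """
    if sd <= 0:
        raise ValueError("sd must be positive (apply the sd floor first)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale == "standard_error":
        return (r - mean) / (sd / math.sqrt(n))
    if scale == "standard_deviation":
        return (r - mean) / sd
    raise ValueError(f"unknown scale {scale!r}")


def alpha_level(t: float, n: int, eps: float = 1e-300, normal_cutoff: int = 30) -> float:
    """Two-sided tail probability of |t|, the per-BSSID match factor.

    Student-t with n-1 degrees of freedom for small samples; the normal
    tail for n above ``normal_cutoff``.  Clamped below at ``eps`` so the
    product over BSSIDs never hits exact zero.
    """
    if n < 2:
        raise ValueError("n must be >= 2 for a t-distribution tail")
    at = abs(t)
    if n > normal_cutoff:
        a = 2.0 * stats.norm.sf(at)
    else:
        a = 2.0 * stats.t.sf(at, df=n - 1)
    return float(min(1.0, max(a, eps)))


def fingerprint_probabilities(
    scan: RssiScan, model: CalibrationModel
) -> LocationEstimate:
    """Posterior-style probability of the scan belonging to each fingerprint.

    For every fingerprint the significance levels are multiplied over the
    model's full BSSID universe (readings the scan lacks are taken at the
    imputation floor), accumulated in the log domain, and normalized so the
    probabilities sum to one.  Winner ties break lexicographically.
    """
    cfg = model.config
    overlap = set(scan.readings) & set(model.bssids)
    if not overlap:
        raise ValueError("scan shares no BSSID with the calibration model")

    ids = model.fingerprint_ids
    log_products = np.empty(len(ids))
    alphas: dict[str, dict[str, float]] = {}
    for j, fid in enumerate(ids):
        per = model.stats[fid]
        acc = 0.0
        a_diag: dict[str, float] = {}
        for bssid in sorted(model.bssids):
            st = per[bssid]
            r = scan.readings.get(bssid, model.floor)
            t = standardize_residual(r, st.mean, st.sd, st.n, cfg.residual_scale)
            a = alpha_level(t, max(st.n, 2), cfg.alpha_eps, cfg.normal_cutoff)
            a_diag[bssid] = a
            acc += math.log(a)
        log_products[j] = acc
        alphas[fid] = a_diag

    log_norm = logsumexp(log_products)
    probs = np.exp(log_products - log_norm)
    probabilities = {fid: float(p) for fid, p in zip(ids, probs)}
    best = max(probabilities.values())
    winner = min(fid for fid, p in probabilities.items() if p == best)
    return LocationEstimate(probabilities=probabilities, winner=winner, alphas=alphas)


def update_track(estimate: LocationEstimate, state: TrackState) -> TrackState:
    """Advance the consecutive-win stabilizer with a new winner.

    The committed position changes only after the same fingerprint wins
    ``k`` consecutive estimates.
    """
    if estimate.winner == state.candidate:
        count = state.count + 1
    else:
        count = 1
    candidate = estimate.winner
    committed = state.committed
    if count >= state.k:
        committed = candidate
        count = state.k
    return replace(state, candidate=candidate, count=count, committed=committed)


def locate(
    scan: RssiScan, model: CalibrationModel, state: TrackState
) -> tuple[LocationEstimate, TrackState]:
    """One localization step: probabilities then track update."""
    estimate = fingerprint_probabilities(scan, model)
    return estimate, update_track(estimate, state)
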