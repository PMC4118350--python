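"""Rule-based cardiac anomaly alerting over beat-feature streams.

Four expert rules run over the interval streams produced by the beat
detector:

* sinus tachycardia — the mean heart rate over an n-beat window of R-R
  intervals exceeds a rate threshold (150 bpm by default):
  ``n * 60000 / sum(rr) > threshold``;
* sinoatrial (SA) block — a P-P interval jumps by more than a pause ratio
  AND is a near-multiple of its predecessor (remainder within a margin);
* sinus pause — the same jump but NOT a near-multiple;
* sinus arrhythmia — R-R variability above a fraction of the mean with the
  dominant oscillation inside the respiratory band (0.15–0.4 Hz).

The SA-block / sinus-pause pair partitions long pauses by the remainder
test, so the two rules can never fire on the same interval pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lombscargle

from .ecg import BeatFeatures

__all__ = [
    "RuleConfig",
    "Alert",
    "tachycardia_rule",
    "sa_block_rule",
    "sinus_pause_rule",
    "sinus_arrhythmia_rule",
    "evaluate_stream",
]

ALERT_TYPES = ("tachycardia", "sa_block", "sinus_pause", "sinus_arrhythmia")


@dataclass(frozen=True)
class RuleConfig:
    """Rule thresholds.

    rate_bpm: tachycardia threshold (strict >).
    window: n, the beat count of the tachycardia window and dedup span.
    pause_ratio: minimum P-P jump treated as a pause.
    margin_ms: e, remainder margin for the near-multiple test.
    symmetric_margin: compare min(rem, prev − rem) so near-multiples are
        recognized from both sides of an exact multiple.
    variability_fraction: (max − min)/mean bound for sinus arrhythmia.
    respiratory_band_hz: where the dominant RR oscillation must lie.
    arrhythmia_window: beat count of the sinus-arrhythmia window (>= 8).
    coherence_min: minimum normalized Lomb-Scargle power at the dominant
        frequency — the oscillation must explain this fraction of the
        detrended window variance, which separates sustained respiratory
        modulation from incoherent beat-to-beat jitter.
    """

    rate_bpm: float = 150.0
    window: int = 5
    pause_ratio: float = 1.5
    margin_ms: float = 50.0
    symmetric_margin: bool = True
    variability_fraction: float = 0.1
    respiratory_band_hz: tuple[float, float] = (0.15, 0.4)
    arrhythmia_window: int = 16
    coherence_min: float = 0.8

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 beats")
        if not (0 < self.variability_fraction < 1):
            raise ValueError("variability fraction must lie in (0, 1)")
        if self.rate_bpm <= 0 or self.pause_ratio <= 0 or self.margin_ms <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class Alert:
    type: str
    time_ms: float
    evidence: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.type not in ALERT_TYPES:
            raise ValueError(f"unknown alert type {self.type!r}")


def tachycardia_rule(
    rr: Sequence[float], k: int, n: int, config: RuleConfig | None = None
) -> bool:
    """Mean rate over rr[k : k+n] strictly above the bpm threshold."""
    config = config or RuleConfig()
    if k < 0 or k + n > len(rr):
        raise ValueError("window out of range")
    window = [float(v) for v in rr[k : k + n]]
    if any(v <= 0 for v in window):
        raise ValueError("R-R intervals must be positive")
    return n * 60000.0 / sum(window) > config.rate_bpm


def _near_multiple(p_prev: float, p_curr: float, config: RuleConfig) -> bool:
    rem = p_curr % p_prev
    if config.symmetric_margin:
        rem = min(rem, p_prev - rem)
    return rem < config.margin_ms


def sa_block_rule(
    p_prev: float, p_curr: float, config: RuleConfig | None = None
) -> bool:
    """Long P-P pause that IS a near-multiple of its predecessor."""
    config = config or RuleConfig()
    if p_prev <= 0 or p_curr <= 0:
        raise ValueError("P-P intervals must be positive")
    return p_curr / p_prev > config.pause_ratio and _near_multiple(
        p_prev, p_curr, config
    )


def sinus_pause_rule(
    p_prev: float, p_curr: float, config: RuleConfig | None = None
) -> bool:
    """Long P-P pause that is NOT a near-multiple of its predecessor."""
    config = config or RuleConfig()
    if p_prev <= 0 or p_curr <= 0:
        raise ValueError("P-P intervals must be positive")
    return p_curr / p_prev > config.pause_ratio and not _near_multiple(
        p_prev, p_curr, config
    )


def sinus_arrhythmia_rule(
    rr: Sequence[float], config: RuleConfig | None = None
) -> bool:
    """Respiratory-band R-R modulation above the variability fraction.

    The beat series is unevenly sampled in time, so the dominant frequency
    of the detrended window comes from a Lomb-Scargle periodogram over the
    cumulative beat times.
    """
    config = config or RuleConfig()
    rr = np.asarray(rr, float)
    if len(rr) < 8:
        raise ValueError("sinus-arrhythmia window needs at least 8 beats")
    mean = float(np.mean(rr))
    if mean <= 0:
        raise ValueError("R-R intervals must be positive")
    if (np.max(rr) - np.min(rr)) / mean <= config.variability_fraction:
        return False
    # respiratory modulation is a gentle oscillation about the median;
    # pause-scale outliers and rate steps belong to the other rules
    med = float(np.median(rr))
    if np.max(rr) > med * config.pause_ratio or np.min(rr) < med / config.pause_ratio:
        return False

    t = np.cumsum(rr) / 1000.0  # beat times, s
    y = rr - np.polyval(np.polyfit(t, rr, 1), t)
    freqs = np.linspace(0.05, 1.0, 400)
    power = lombscargle(t, y, 2.0 * np.pi * freqs, normalize=True)
    peak = int(np.argmax(power))
    dominant = float(freqs[peak])
    lo, hi = config.respiratory_band_hz
    return lo <= dominant <= hi and float(power[peak]) >= config.coherence_min


def evaluate_stream(
    features: Sequence[BeatFeatures], config: RuleConfig | None = None
) -> list[Alert]:
    """Slide all rules over a beat-feature stream and emit deduplicated alerts.

    At most one alert of a given type is emitted per ``window`` consecutive
    beats; SA block and sinus pause are mutually exclusive per interval pair
    by construction of the remainder split.
    """
    config = config or RuleConfig()
    rr: list[float] = [f.ri for f in features if f.ri is not None]
    rr_time: list[float] = list(np.cumsum(rr))
    pp: list[tuple[float, float]] = []  # (interval ms, cumulative time ms)
    acc = 0.0
    for f in features:
        if f.pi is not None:
            acc += f.pi
            pp.append((f.pi, acc))

    alerts: list[Alert] = []
    last_trigger: dict[str, int] = {}

    def emit(kind: str, beat: int, time_ms: float, evidence: Sequence[float]) -> None:
        # chain-dedup: triggers within `window` beats of the previous trigger
        # belong to the same episode and extend it without a new alert
        prev = last_trigger.get(kind)
        last_trigger[kind] = beat
        if prev is not None and beat - prev < config.window:
            return
        alerts.append(Alert(type=kind, time_ms=float(time_ms), evidence=tuple(evidence)))

    n = config.window
    for k in range(0, max(len(rr) - n + 1, 0)):
        if tachycardia_rule(rr, k, n, config):
            emit("tachycardia", k + n - 1, rr_time[k + n - 1], rr[k : k + n])

    for i in range(1, len(pp)):
        prev, curr = pp[i - 1][0], pp[i][0]
        if sa_block_rule(prev, curr, config):
            emit("sa_block", i, pp[i][1], (prev, curr))
        elif sinus_pause_rule(prev, curr, config):
            emit("sinus_pause", i, pp[i][1], (prev, curr))

    w = config.arrhythmia_window
    for k in range(0, max(len(rr) - w + 1, 0)):
        if sinus_arrhythmia_rule(rr[k : k + w], config):
            emit("sinus_arrhythmia", k + w - 1, rr_time[k + w - 1], rr[k : k + w])

    alerts.sort(key=lambda a: (a.time_ms, a.type))
    return alerts
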