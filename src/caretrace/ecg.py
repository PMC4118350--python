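"""Single-lead ECG beat detection and beat-feature extraction.

QRS complexes are found with a four-stage pipeline in the Pan-Tompkins
tradition: (1) wavelet soft-threshold denoising, (2) linear highpass to
remove baseline wander, (3) a non-linear lowpass (squaring followed by
moving-window integration) producing a non-negative energy envelope, and
(4) peak decision against an adaptive threshold

    tr <- alpha * gamma * peak + (1 - alpha) * tr

updated at every accepted peak.  Q/S are located as the window minima
flanking each R, P/T as window extrema before Q and after S, and per-beat
features are inter-beat same-wave intervals plus intra-beat distances in
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import signal as sp_signal

__all__ = [
    "EcgSignal",
    "DetectorParams",
    "BeatAnnotation",
    "BeatFeatures",
    "preprocess",
    "update_threshold",
    "detect_r_peaks",
    "locate_waves",
    "beat_features",
]


@dataclass(frozen=True)
class EcgSignal:
    """Uniformly sampled single-lead ECG in millivolts."""

    rate: float  # Hz
    samples: np.ndarray  # mV

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        samples = np.asarray(self.samples, float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("non-finite ECG sample")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class DetectorParams:
    """Pipeline tunables.

    The defaults are this package's choices: db4 wavelet with the removed
    detail bands above ``denoise_above_hz``; a 5 Hz second-order Butterworth
    highpass; 150 ms integration window; threshold constants alpha = 0.1,
    gamma = 0.5; 200 ms refractory period; 60 ms Q/S half-window; 200 ms
    P-search window before Q and 400 ms T-search window after S.
    """

    wavelet: str = "db4"
    denoise_above_hz: float = 45.0
    highpass_hz: float = 5.0
    integration_ms: float = 150.0
    alpha: float = 0.1
    gamma: float = 0.5
    refractory_ms: float = 200.0
    qs_half_window_ms: float = 60.0
    p_window_ms: float = 200.0
    t_window_ms: float = 400.0
    refine_ms: float = 50.0
    prominence_floor_mv: float = 0.05
    tr_init_s: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.gamma <= 1):
            raise ValueError("alpha and gamma must lie in (0, 1]")
        if self.refractory_ms <= 0:
            raise ValueError("refractory period must be positive")


@dataclass(frozen=True)
class BeatAnnotation:
    """Sample indices of the five waves; P and T may be absent."""

    r: int
    q: int
    s: int
    p: Optional[int] = None
    t: Optional[int] = None

    def __post_init__(self) -> None:
        order = [i for i in (self.p, self.q, self.r, self.s, self.t) if i is not None]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError(f"wave indices out of order: {order}")


@dataclass(frozen=True)
class BeatFeatures:
    """Interval vector for one beat, all in milliseconds.

    ``pi..ti`` are distances to the same wave in the previous beat (None for
    the first beat or when either wave is absent); ``dpq..dst`` are
    intra-beat distances.
    """

    pi: Optional[float]
    qi: Optional[float]
    ri: Optional[float]
    si: Optional[float]
    ti: Optional[float]
    dpq: Optional[float]
    dqr: float
    drs: float
    dst: Optional[float]


def _denoise_levels(rate: float, above_hz: float) -> int:
    # detail band k spans rate/2^(k+1) .. rate/2^k; strip bands lying above the cut
    levels = 0
    while rate / 2 ** (levels + 2) >= above_hz:
        levels += 1
    return max(levels, 1)


def preprocess(sig: EcgSignal, params: DetectorParams | None = None) -> np.ndarray:
    """Produce the non-negative QRS energy envelope (same length as input)."""
    params = params or DetectorParams()
    x = sig.samples
    win = max(int(round(params.integration_ms / 1000.0 * sig.rate)), 1)
    if len(x) < win:
        raise ValueError("signal shorter than one integration window")

    # (1) wavelet soft-threshold denoising of the high-frequency detail bands
    levels = _denoise_levels(sig.rate, params.denoise_above_hz)
    maxlev = pywt.dwt_max_level(len(x), pywt.Wavelet(params.wavelet).dec_len)
    levels = min(levels, maxlev)
    if levels >= 1:
        coeffs = pywt.wavedec(x, params.wavelet, level=levels)
        d1 = coeffs[-1]
        sigma = np.median(np.abs(d1)) / 0.6745 if len(d1) else 0.0
        thr = sigma * math.sqrt(2.0 * math.log(max(len(x), 2)))
        if thr > 0:
            coeffs[1:] = [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
            x = pywt.waverec(coeffs, params.wavelet)[: len(sig.samples)]

    # (2) linear highpass removes DC and baseline wander
    nyq = sig.rate / 2.0
    b, a = sp_signal.butter(2, params.highpass_hz / nyq, btype="highpass")
    x = sp_signal.filtfilt(b, a, x)

    # (3) non-linear lowpass: square + moving-window integration
    x = x * x
    kernel = np.ones(win) / win
    env = np.convolve(x, kernel, mode="same")
    return env


def update_threshold(tr: float, peak: float, alpha: float, gamma: float) -> float:
    """One adaptive-threshold update: alpha*gamma*peak + (1-alpha)*tr."""
    if tr < 0 or peak < 0:
        raise ValueError("threshold and peak must be non-negative")
    return alpha * gamma * peak + (1.0 - alpha) * tr


def detect_r_peaks(
    envelope: np.ndarray, sig: EcgSignal, params: DetectorParams | None = None
) -> np.ndarray:
    """R-peak sample indices from the energy envelope.

    Envelope local maxima above the running threshold, at least one
    refractory period apart, each refined to the raw-signal maximum within
    ``refine_ms`` of the envelope peak.  The threshold starts at gamma times
    the envelope maximum over the first ``tr_init_s`` seconds, which makes
    the decision invariant under positive amplitude scaling of the input.
    """
    params = params or DetectorParams()
    env = np.asarray(envelope, float)
    refractory = int(round(params.refractory_ms / 1000.0 * sig.rate))
    refine = int(round(params.refine_ms / 1000.0 * sig.rate))

    init_n = min(len(env), max(int(round(params.tr_init_s * sig.rate)), 1))
    tr = params.gamma * float(np.max(env[:init_n]))
    if tr == 0.0:
        return np.empty(0, dtype=int)

    candidates, _ = sp_signal.find_peaks(env, distance=max(refractory, 1))
    accepted: list[int] = []
    last = -np.inf
    for idx in candidates:
        if env[idx] <= tr or idx - last < refractory:
            continue
        lo = max(0, idx - refine)
        hi = min(len(sig.samples), idx + refine + 1)
        r_idx = lo + int(np.argmax(sig.samples[lo:hi]))
        accepted.append(r_idx)
        last = idx
        tr = update_threshold(tr, float(env[idx]), params.alpha, params.gamma)
    return np.unique(np.asarray(accepted, dtype=int))


def locate_waves(
    sig: EcgSignal,
    r_indices: Sequence[int],
    params: DetectorParams | None = None,
) -> list[BeatAnnotation]:
    """Locate Q, S, P and T around each R by interval search.

    Q and S are the minima in the half-windows flanking R.  P is the
    maximum in a window before Q, T the maximum in a window after S; both
    are marked absent when the extremum fails to rise above the window
    median by the prominence floor.  Beats whose Q/S windows would be
    truncated by the record edge are dropped.
    """
    params = params or DetectorParams()
    x = sig.samples
    qs = max(int(round(params.qs_half_window_ms / 1000.0 * sig.rate)), 1)
    p_w = max(int(round(params.p_window_ms / 1000.0 * sig.rate)), 1)
    t_w = max(int(round(params.t_window_ms / 1000.0 * sig.rate)), 1)

    beats: list[BeatAnnotation] = []
    for r in sorted(int(r) for r in r_indices):
        if r - qs < 0 or r + qs >= len(x):
            continue  # truncated QRS window
        q = r - qs + int(np.argmin(x[r - qs : r]))
        s = r + 1 + int(np.argmin(x[r + 1 : r + qs + 1]))

        p: Optional[int] = None
        lo = max(0, q - p_w)
        if q - lo >= 2:
            seg = x[lo:q]
            cand = lo + int(np.argmax(seg))
            if x[cand] - float(np.median(seg)) >= params.prominence_floor_mv:
                p = cand

        t: Optional[int] = None
        hi = min(len(x), s + 1 + t_w)
        if hi - (s + 1) >= 2:
            seg = x[s + 1 : hi]
            cand = s + 1 + int(np.argmax(seg))
            if x[cand] - float(np.median(seg)) >= params.prominence_floor_mv:
                t = cand

        beats.append(BeatAnnotation(r=r, q=q, s=s, p=p, t=t))
    return beats


def beat_features(
    annotations: Sequence[BeatAnnotation], rate: float
) -> list[BeatFeatures]:
    """Convert annotations to the per-beat interval vector in milliseconds."""
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    ms = 1000.0 / rate

    def delta(curr: Optional[int], prev: Optional[int]) -> Optional[float]:
        if curr is None or prev is None:
            return None
        return (curr - prev) * ms

    out: list[BeatFeatures] = []
    prev: Optional[BeatAnnotation] = None
    for ann in annotations:
        out.append(
            BeatFeatures(
                pi=delta(ann.p, prev.p if prev else None),
                qi=delta(ann.q, prev.q if prev else None),
                ri=delta(ann.r, prev.r if prev else None),
                si=delta(ann.s, prev.s if prev else None),
                ti=delta(ann.t, prev.t if prev else None),
                dpq=delta(ann.q, ann.p),
                dqr=(ann.r - ann.q) * ms,
                drs=(ann.s - ann.r) * ms,
                dst=delta(ann.t, ann.s),
            )
        )
        prev = ann
    return out
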