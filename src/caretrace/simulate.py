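"""Ground-truthed synthetic fixtures for every pipeline.

Three generators, all seed-deterministic:

* ``simulate_rssi`` — a 2-D flat with access points and fingerprint
  positions; RSSI follows a log-distance path-loss model with Gaussian
  shadowing, truncated to the receiver's dynamic range.
* ``simulate_walk`` — tri-axial accelerometer traces whose force magnitude
  oscillates about gravity during walking bouts, with true step times.
* ``simulate_ecg`` — beats as sums of five Gaussian bumps (P, Q, R, S, T)
  on a scripted R-R sequence, with pathology injectors (tachycardia
  episode, dropped beat doubling one P-P interval, non-multiple pause,
  respiratory R-R modulation) and true wave sample indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ecg import BeatAnnotation, EcgSignal
from .rssi import Fingerprint, RssiScan
from .steps import StepEvent

__all__ = [
    "RssiEnvironment",
    "EcgScript",
    "TachycardiaEpisode",
    "DroppedBeat",
    "SinusPause",
    "RespiratoryModulation",
    "simulate_rssi",
    "simulate_walk",
    "simulate_ecg",
    "default_environment",
]


@dataclass(frozen=True)
class RssiEnvironment:
    """A flat: AP positions, fingerprint positions, and a path-loss model.

    RSSI at distance d (m) is ``p0 - 10 * exponent * log10(d)`` plus
    Gaussian shadowing noise, truncated to [-100, -20] dBm.
    """

    ap_positions: tuple[tuple[float, float], ...]
    fingerprint_positions: tuple[tuple[float, float], ...]
    fingerprint_ids: tuple[str, ...]
    p0: float = -40.0  # dBm at 1 m
    exponent: float = 2.5
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.ap_positions) < 1:
            raise ValueError("need at least one access point")
        if len(self.fingerprint_positions) < 2:
            raise ValueError("need at least two fingerprints")
        if len(self.fingerprint_ids) != len(self.fingerprint_positions):
            raise ValueError("fingerprint ids and positions differ in length")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def default_environment(noise_sd: float = 2.0) -> RssiEnvironment:
    """Three access points and six rooms laid out over a ~12x8 m flat."""
    return RssiEnvironment(
        ap_positions=((0.5, 0.5), (11.5, 0.5), (6.0, 7.5)),
        fingerprint_positions=(
            (2.0, 2.0),
            (6.0, 2.0),
            (10.0, 2.0),
            (2.0, 6.0),
            (6.0, 6.0),
            (10.0, 6.0),
        ),
        fingerprint_ids=("kitchen", "hall", "living", "bath", "bed1", "bed2"),
        noise_sd=noise_sd,
    )


def _rssi_at(env: RssiEnvironment, pos: tuple[float, float], rng: np.random.Generator) -> dict[str, float]:
    readings: dict[str, float] = {}
    for k, ap in enumerate(env.ap_positions):
        d = math.hypot(pos[0] - ap[0], pos[1] - ap[1])
        d = max(d, 0.1)  # guard against coincident AP/fingerprint
        rssi = env.p0 - 10.0 * env.exponent * math.log10(d)
        if env.noise_sd > 0:
            rssi += rng.normal(0.0, env.noise_sd)
        readings[f"ap{k:02d}"] = float(np.clip(rssi, -100.0, -20.0))
    return readings


def simulate_rssi(
    env: RssiEnvironment,
    scans_per_fingerprint: int = 50,
    test_scans_per_fingerprint: int = 50,
    seed: int = 0,
) -> tuple[list[Fingerprint], list[tuple[str, RssiScan]]]:
    """Generate a calibration set plus labeled held-out test scans.

    Returns ``(fingerprints, test)`` where ``test`` is a list of
    (true fingerprint id, scan) pairs drawn from the same model with fresh
    noise — the synthetic analogue of re-visiting each position later.
    """
    rng = np.random.default_rng(seed)
    fingerprints: list[Fingerprint] = []
    for fid, pos in zip(env.fingerprint_ids, env.fingerprint_positions):
        scans = [
            RssiScan(readings=_rssi_at(env, pos, rng), timestamp=float(j))
            for j in range(scans_per_fingerprint)
        ]
        fingerprints.append(Fingerprint(id=fid, scans=scans))
    test: list[tuple[str, RssiScan]] = []
    for fid, pos in zip(env.fingerprint_ids, env.fingerprint_positions):
        for j in range(test_scans_per_fingerprint):
            test.append((fid, RssiScan(readings=_rssi_at(env, pos, rng), timestamp=float(j))))
    return fingerprints, test


def simulate_walk(
    step_count: int = 20,
    cadence_hz: float = 2.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    rate_hz: float = 50.0,
    rest_s: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[StepEvent]]:
    """A walking bout flanked by rest, with true step times.

    The force magnitude is ``9.81 + amplitude * sin(2*pi*cadence*t)`` during
    the bout and 9.81 at rest, plus Gaussian noise; the whole magnitude is
    carried on the z axis so the vector norm reproduces it exactly.  One
    step per gait cycle; the true step time is the cycle's trough (the
    lower-threshold crossing region).

    Returns ``(t, xyz, true_steps)`` with ``xyz`` of shape (n, 3).
    """
    if step_count < 0 or cadence_hz <= 0 or amplitude < 0 or rate_hz <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    bout = step_count / cadence_hz
    total = rest_s + bout + rest_s
    t = np.arange(0.0, total, 1.0 / rate_hz)
    mag = np.full_like(t, 9.81)
    in_bout = (t >= rest_s) & (t < rest_s + bout)
    mag[in_bout] += amplitude * np.sin(2.0 * np.pi * cadence_hz * (t[in_bout] - rest_s))
    if noise_sd > 0:
        mag = mag + rng.normal(0.0, noise_sd, size=mag.shape)
    xyz = np.zeros((len(t), 3))
    xyz[:, 2] = mag
    truth = [
        StepEvent(t=rest_s + (k + 0.75) / cadence_hz) for k in range(step_count)
    ]
    return t, xyz, truth


@dataclass(frozen=True)
class TachycardiaEpisode:
    start_s: float
    end_s: float
    rate_bpm: float = 160.0


@dataclass(frozen=True)
class DroppedBeat:
    at_s: float  # the beat nearest this time is skipped -> doubled P-P


@dataclass(frozen=True)
class SinusPause:
    at_s: float
    ratio: float = 1.7  # non-multiple prolongation of one interval


@dataclass(frozen=True)
class RespiratoryModulation:
    freq_hz: float = 0.25
    fraction: float = 0.15  # peak fractional R-R deviation


@dataclass(frozen=True)
class EcgScript:
    """Everything needed to synthesize one ECG record."""

    duration_s: float = 10.0
    base_rate_bpm: float = 60.0
    rr_jitter_fraction: float = 0.0
    rate_hz: float = 256.0
    noise_sd_mv: float = 0.0
    seed: int = 0
    tachycardia: Optional[TachycardiaEpisode] = None
    dropped_beat: Optional[DroppedBeat] = None
    pause: Optional[SinusPause] = None
    respiration: Optional[RespiratoryModulation] = None
    # morphology: (amplitude mV, width ms, offset ms from R) per wave
    p_wave: tuple[float, float, float] = (0.15, 25.0, -160.0)
    q_wave: tuple[float, float, float] = (-0.15, 10.0, -25.0)
    r_wave: tuple[float, float, float] = (1.0, 10.0, 0.0)
    s_wave: tuple[float, float, float] = (-0.15, 10.0, 25.0)
    t_wave: tuple[float, float, float] = (0.3, 60.0, 250.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.base_rate_bpm <= 0 or self.rate_hz <= 0:
            raise ValueError("duration, rate and sampling rate must be positive")
        events = []
        if self.tachycardia:
            if not (0 <= self.tachycardia.start_s < self.tachycardia.end_s <= self.duration_s):
                raise ValueError("tachycardia episode outside the record")
            events.append((self.tachycardia.start_s, self.tachycardia.end_s))
        for ev in (self.dropped_beat, self.pause):
            if ev is not None:
                if not (0 <= ev.at_s <= self.duration_s):
                    raise ValueError("event outside the record")
                events.append((ev.at_s, ev.at_s))
        events.sort()
        for (s0, e0), (s1, e1) in zip(events, events[1:]):
            if s1 < e0:
                raise ValueError("overlapping pathology events")


def _beat_times(script: EcgScript, rng: np.random.Generator) -> list[float]:
    times: list[float] = []
    t = 0.3  # leave room for the first P wave
    drop_done = pause_done = False
    while t < script.duration_s - 0.4:
        times.append(t)
        rate = script.base_rate_bpm
        if script.tachycardia and script.tachycardia.start_s <= t < script.tachycardia.end_s:
            rate = script.tachycardia.rate_bpm
        rr = 60.0 / rate
        if script.respiration:
            rr *= 1.0 + script.respiration.fraction * math.sin(
                2.0 * math.pi * script.respiration.freq_hz * t
            )
        if script.rr_jitter_fraction > 0:
            rr *= 1.0 + rng.normal(0.0, script.rr_jitter_fraction)
        if script.dropped_beat and not drop_done and t >= script.dropped_beat.at_s:
            rr *= 2.0  # skipped beat: next interval exactly doubles
            drop_done = True
        elif script.pause and not pause_done and t >= script.pause.at_s:
            rr *= script.pause.ratio
            pause_done = True
        t += rr
    return times


def simulate_ecg(script: EcgScript) -> tuple[EcgSignal, list[BeatAnnotation]]:
    """Synthesize the record and its ground-truth annotations."""
    rng = np.random.default_rng(script.seed)
    n = int(round(script.duration_s * script.rate_hz))
    tt = np.arange(n) / script.rate_hz
    x = np.zeros(n)

    beat_times = _beat_times(script, rng)
    waves = {
        "p": script.p_wave,
        "q": script.q_wave,
        "r": script.r_wave,
        "s": script.s_wave,
        "t": script.t_wave,
    }
    truth: list[BeatAnnotation] = []
    for bt in beat_times:
        idx: dict[str, Optional[int]] = {}
        for name, (amp, width_ms, offset_ms) in waves.items():
            center = bt + offset_ms / 1000.0
            if amp != 0.0:
                w = width_ms / 1000.0
                x += amp * np.exp(-0.5 * ((tt - center) / w) ** 2)
            i = int(round(center * script.rate_hz))
            idx[name] = i if (amp != 0.0 and 0 <= i < n) else None
        if idx["q"] is None or idx["r"] is None or idx["s"] is None:
            continue
        truth.append(
            BeatAnnotation(r=idx["r"], q=idx["q"], s=idx["s"], p=idx["p"], t=idx["t"])
        )

    if script.noise_sd_mv > 0:
        x = x + rng.normal(0.0, script.noise_sd_mv, size=n)
    return EcgSignal(rate=script.rate_hz, samples=x), truth
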