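"""File formats and run configuration.

Conventions: comma-separated CSV with a header row, UTF-8, '.' decimal;
JSON for nested structures (calibration sets, models); JSON-lines for
event streams (alerts, session logs).  Loaders validate the domain
invariants and name the offending row in error messages.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ecg import BeatAnnotation, BeatFeatures, EcgSignal
from .rssi import (
    BssidStats,
    CalibrationConfig,
    CalibrationModel,
    Fingerprint,
    RssiScan,
)
from .rules import Alert

__all__ = [
    "load_calibration",
    "save_calibration",
    "load_model",
    "save_model",
    "load_scan_stream",
    "save_scan_stream",
    "load_accel",
    "save_accel",
    "load_ecg",
    "save_ecg",
    "save_annotations",
    "load_annotations",
    "save_features",
    "load_features",
    "save_alerts",
    "load_alerts",
    "load_inputs",
    "RunConfig",
]

FEATURE_COLUMNS = ["pi", "qi", "ri", "si", "ti", "dpq", "dqr", "drs", "dst"]


def _err(path: Path | str, where: str, msg: str) -> ValueError:
    return ValueError(f"{path}: {where}: {msg}")


# --- calibration sets ------------------------------------------------------

def save_calibration(fingerprints: Sequence[Fingerprint], path: str | Path) -> None:
    doc = {
        "fingerprints": [
            {
                "id": fp.id,
                "scans": [
                    {"timestamp": s.timestamp, "readings": dict(s.readings)}
                    for s in fp.scans
                ],
            }
            for fp in fingerprints
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_calibration(path: str | Path) -> list[Fingerprint]:
    doc = json.loads(Path(path).read_text())
    if "fingerprints" not in doc:
        raise _err(path, "top level", "missing 'fingerprints' key")
    out: list[Fingerprint] = []
    for i, fpd in enumerate(doc["fingerprints"]):
        where = f"fingerprint #{i}"
        try:
            scans = [
                RssiScan(
                    readings={str(b): float(r) for b, r in sd["readings"].items()},
                    timestamp=sd.get("timestamp"),
                )
                for sd in fpd["scans"]
            ]
            out.append(Fingerprint(id=str(fpd["id"]), scans=scans))
        except (KeyError, TypeError, ValueError) as exc:
            raise _err(path, where, str(exc)) from exc
    ids = [fp.id for fp in out]
    if len(set(ids)) != len(ids):
        raise _err(path, "calibration set", "duplicate fingerprint ids")
    return out


# --- calibration model -----------------------------------------------------

def save_model(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "config": dataclasses.asdict(model.config),
        "floor": model.floor,
        "bssids": sorted(model.bssids),
        "fingerprints": {
            fid: {
                b: dataclasses.asdict(st) for b, st in sorted(per.items())
            }
            for fid, per in model.stats.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    try:
        config = CalibrationConfig(**doc["config"])
        stats = {
            fid: {b: BssidStats(**st) for b, st in per.items()}
            for fid, per in doc["fingerprints"].items()
        }
        return CalibrationModel(
            stats=stats,
            bssids=frozenset(doc["bssids"]),
            floor=float(doc["floor"]),
            config=config,
        )
    except (KeyError, TypeError) as exc:
        raise _err(path, "model", str(exc)) from exc


# --- scan streams ----------------------------------------------------------

def save_scan_stream(scans: Sequence[RssiScan], path: str | Path) -> None:
    rows = []
    for i, scan in enumerate(scans):
        ts = scan.timestamp if scan.timestamp is not None else float(i)
        for bssid, rssi in sorted(scan.readings.items()):
            rows.append({"timestamp": ts, "bssid": bssid, "rssi": rssi})
    pd.DataFrame(rows, columns=["timestamp", "bssid", "rssi"]).to_csv(
        path, index=False
    )


def load_scan_stream(path: str | Path) -> list[RssiScan]:
    df = pd.read_csv(path)
    for col in ("timestamp", "bssid", "rssi"):
        if col not in df.columns:
            raise _err(path, "header", f"missing column {col!r}")
    bad = df[pd.to_numeric(df["rssi"], errors="coerce").isna()]
    if len(bad):
        raise _err(path, f"row {bad.index[0] + 2}", "non-numeric RSSI")
    scans = []
    for ts, grp in df.groupby("timestamp", sort=True):
        scans.append(
            RssiScan(
                readings=dict(zip(grp["bssid"].astype(str), grp["rssi"].astype(float))),
                timestamp=float(ts),
            )
        )
    return scans


# --- accelerometer ---------------------------------------------------------

def save_accel(t: np.ndarray, xyz: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"t": t, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
    ).to_csv(path, index=False)


def load_accel(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "z"):
        if col not in df.columns:
            raise _err(path, "header", f"missing column {col!r}")
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise _err(path, f"row {bad.index[0] + 2}", f"non-numeric {col!r}")
    t = df["t"].to_numpy(float)
    if t.size and np.any(np.diff(t) <= 0):
        raise _err(path, "column t", "timestamps not strictly increasing")
    return t, df[["x", "y", "z"]].to_numpy(float)


# --- ECG -------------------------------------------------------------------

def save_ecg(sig: EcgSignal, path: str | Path) -> None:
    t = np.arange(len(sig.samples)) / sig.rate
    pd.DataFrame({"t": t, "mv": sig.samples}).to_csv(path, index=False)


def load_ecg(path: str | Path, rate: Optional[float] = None) -> EcgSignal:
    df = pd.read_csv(path)
    if "mv" not in df.columns:
        raise _err(path, "header", "missing column 'mv'")
    if "t" in df.columns:
        t = df["t"].to_numpy(float)
        if len(t) < 2:
            raise _err(path, "column t", "need at least two samples")
        inferred = 1.0 / float(np.median(np.diff(t)))
        rate = rate or inferred
    elif rate is None:
        raise _err(path, "header", "no 't' column; a sampling rate is required")
    return EcgSignal(rate=float(rate), samples=df["mv"].to_numpy(float))


def save_annotations(beats: Sequence[BeatAnnotation], path: str | Path) -> None:
    rows = [
        {"beat": i, "p": b.p, "q": b.q, "r": b.r, "s": b.s, "t": b.t}
        for i, b in enumerate(beats)
    ]
    pd.DataFrame(rows, columns=["beat", "p", "q", "r", "s", "t"]).to_csv(
        path, index=False
    )


def load_annotations(path: str | Path) -> list[BeatAnnotation]:
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        def opt(v):
            return None if pd.isna(v) else int(v)
        try:
            out.append(
                BeatAnnotation(
                    r=int(row["r"]), q=int(row["q"]), s=int(row["s"]),
                    p=opt(row.get("p")), t=opt(row.get("t")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise _err(path, f"row {i + 2}", str(exc)) from exc
    return out


def save_features(features: Sequence[BeatFeatures], path: str | Path) -> None:
    rows = [
        {"beat": i, **{c: getattr(f, c) for c in FEATURE_COLUMNS}}
        for i, f in enumerate(features)
    ]
    pd.DataFrame(rows, columns=["beat"] + FEATURE_COLUMNS).to_csv(path, index=False)


def load_features(path: str | Path) -> list[BeatFeatures]:
    df = pd.read_csv(path)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise _err(path, "header", f"missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        vals = {
            c: (None if pd.isna(row[c]) else float(row[c])) for c in FEATURE_COLUMNS
        }
        out.append(BeatFeatures(**vals))
    return out


# --- alerts ----------------------------------------------------------------

def save_alerts(alerts: Sequence[Alert], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alerts:
            fh.write(
                json.dumps(
                    {"type": a.type, "time_ms": a.time_ms, "evidence": list(a.evidence)},
                    sort_keys=True,
                )
                + "\n"
            )


def load_alerts(path: str | Path) -> list[Alert]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        try:
            d = json.loads(line)
            out.append(
                Alert(
                    type=d["type"],
                    time_ms=float(d["time_ms"]),
                    evidence=tuple(d.get("evidence", ())),
                )
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise _err(path, f"line {i + 1}", str(exc)) from exc
    return out


_LOADERS = {
    "calibration": load_calibration,
    "scans": load_scan_stream,
    "accel": load_accel,
    "ecg": load_ecg,
    "features": load_features,
    "alerts": load_alerts,
}


def load_inputs(path: str | Path, kind: str) -> Any:
    """Load a dataset of the given kind with invariant validation."""
    if kind not in _LOADERS:
        raise ValueError(f"unknown input kind {kind!r}; one of {sorted(_LOADERS)}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return _LOADERS[kind](path)


# --- run configuration -----------------------------------------------------

_CONFIG_BLOCKS = {
    "location": ("sd_floor", "floor_factor", "pseudo_count", "residual_scale",
                 "alpha_eps", "normal_cutoff", "quartile_method", "k"),
    "steps": ("upper", "lower", "timeout", "smooth_window"),
    "ecg": ("wavelet", "denoise_above_hz", "highpass_hz", "integration_ms",
            "alpha", "gamma", "refractory_ms", "qs_half_window_ms",
            "p_window_ms", "t_window_ms", "refine_ms", "prominence_floor_mv",
            "tr_init_s", "rate"),
    "rules": ("rate_bpm", "window", "pause_ratio", "margin_ms",
              "symmetric_margin", "variability_fraction",
              "respiratory_band_hz", "arrhythmia_window"),
    "monitor": ("alert_dedup_s",),
    "simulate": ("scans_per_fingerprint", "noise_sd", "step_count",
                 "cadence_hz", "amplitude", "duration_s", "base_rate_bpm"),
    "benchmark": ("reps", "scans_per_fingerprint", "bin_width_dbm"),
}


class RunConfig:
    """Validated run configuration with all defaults materialized.

    Unknown top-level sections or keys inside a section are rejected.  The
    full materialized mapping is echoed next to outputs so any run can be
    reproduced exactly from its output directory.
    """

    def __init__(self, raw: Optional[dict] = None, seed: int = 0,
                 log_level: str = "INFO") -> None:
        raw = raw or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        unknown = set(raw) - set(_CONFIG_BLOCKS) - {"seed", "log_level"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        self.blocks: dict[str, dict] = {}
        for block, allowed in _CONFIG_BLOCKS.items():
            given = raw.get(block, {})
            if not isinstance(given, dict):
                raise ValueError(f"config section {block!r} must be a mapping")
            bad = set(given) - set(allowed)
            if bad:
                raise ValueError(f"unknown key(s) in {block!r}: {sorted(bad)}")
            self.blocks[block] = dict(given)
        self.seed = int(raw.get("seed", seed))
        self.log_level = str(raw.get("log_level", log_level))

    @classmethod
    def from_yaml(cls, path: str | Path, **kwargs) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(raw, **kwargs)

    def echo(self, path: str | Path) -> None:
        doc = {"seed": self.seed, "log_level": self.log_level, **self.blocks}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
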