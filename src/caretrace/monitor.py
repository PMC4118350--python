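"""Offline monitoring loop: motion-gated localization plus alert routing.

The committed WiFi position is allowed to change only while the step
detector reports motion; when the user has been still for longer than the
timeout, the position freezes (RSSI fluctuation alone cannot move it).
Cardiac alerts are appended to a session log with per-type deduplication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .rssi import TrackState
from .rules import Alert

__all__ = ["MonitorState", "fuse", "dispatch", "session_log_lines"]


@dataclass(frozen=True)
class MonitorState:
    position: Optional[str] = None
    alert_log: tuple[Alert, ...] = field(default_factory=tuple)
    alert_dedup_s: float = 60.0


def fuse(track: TrackState, motion: str, state: MonitorState) -> MonitorState:
    """Update the monitored position from the localization track.

    The committed track position propagates only while ``motion`` is
    'moving'; a stationary user keeps the last position.
    """
    if motion not in ("moving", "stationary"):
        raise ValueError(f"unknown motion state {motion!r}")
    if motion == "moving" and track.committed is not None:
        return replace(state, position=track.committed)
    return state


def dispatch(alerts: Sequence[Alert], state: MonitorState) -> MonitorState:
    """Append alerts to the log, deduplicating same-type alerts in a window."""
    log = list(state.alert_log)
    for alert in alerts:
        dup = any(
            prev.type == alert.type
            and abs(alert.time_ms - prev.time_ms) < state.alert_dedup_s * 1000.0
            for prev in log
        )
        if not dup:
            log.append(alert)
    log.sort(key=lambda a: (a.time_ms, a.type))
    return replace(state, alert_log=tuple(log))


def session_log_lines(
    events: Sequence[tuple[float, Optional[str], str, Sequence[Alert]]]
) -> list[str]:
    """Render (t, position, motion, alerts) tuples as JSON lines.

    Deterministic: replaying the same event stream yields byte-identical
    output.
    """
    lines = []
    for t, position, motion, alerts in events:
        lines.append(
            json.dumps(
                {
                    "t": t,
                    "position": position,
                    "moving": motion == "moving",
                    "alerts": [
                        {"type": a.type, "time_ms": a.time_ms, "evidence": list(a.evidence)}
                        for a in alerts
                    ],
                },
                sort_keys=True,
            )
        )
    return lines
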