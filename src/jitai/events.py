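"""JSONL deployment event log.

One event per line: ``{"timestamp": ISO-8601, "participant_id": str,
"event_type": str, "payload": {...}}``.  Event types emitted by the
simulator / consumed by the feature builder:

==========================  =================================================
participant_enrolled        full participant profile
ema_prompt / ema_response   EMA prompt shown / 1-5 stress rating answered
context_window              half-hour telemetry aggregate (timestamp = slot)
stress_score                per-tick composite score (optional, bulky)
nudge_sent                  {nudge_id, source, score, thresholds, latest_ema}
nudge_postponed             {nudge_id, until}
nudge_expired               {nudge_id}
category_chosen             {nudge_id, category}
pre_stress_reported         {nudge_id, value}
intervention_assigned       {nudge_id, intervention_id, category, modality,
                             location}
intervention_done           {nudge_id}
intervention_rated          {nudge_id, value}
post_stress_reported        {nudge_id, value}
flow_abandoned              {nudge_id}
==========================  =================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

TIME_FMT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class Event:
    timestamp: datetime
    participant_id: str
    event_type: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp.strftime(TIME_FMT),
                "participant_id": self.participant_id,
                "event_type": self.event_type,
                "payload": self.payload,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "Event":
        d = json.loads(line)
        return cls(
            timestamp=datetime.strptime(d["timestamp"], TIME_FMT),
            participant_id=d["participant_id"],
            event_type=d["event_type"],
            payload=d.get("payload", {}),
        )


def sort_events(events: Iterable[Event]) -> list[Event]:
    """Stable global time order (ties broken by participant then type)."""
    return sorted(events, key=lambda e: (e.timestamp, e.participant_id, e.event_type))


def write_jsonl(events: Iterable[Event], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_jsonl(path: str | Path) -> Iterator[Event]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Event.from_json(line)


def to_csv(events: Iterable[Event], path: str | Path) -> None:
    """Flat CSV mirror of the event log (payload flattened to columns)."""
    rows = []
    for ev in events:
        row = {
            "timestamp": ev.timestamp.strftime(TIME_FMT),
            "participant_id": ev.participant_id,
            "event_type": ev.event_type,
        }
        for k, v in ev.payload.items():
            row[f"payload_{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
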