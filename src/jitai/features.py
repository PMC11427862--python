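"""Feature builder: from a deployment event log to analysis tables.

Reconstructs the three tables the outcome models are fitted on:

* **per-nudge** — one row per system-initiated nudge (JIT or rescheduled),
  joining participant traits, the half-hour telemetry window holding the
  nudge timestamp, per-participant engagement skewness and per-slot nudge
  probability, and the engaged label;
* **chosen** — the subset where a category was selected, with the
  intervention's category/modality/location;
* **completed** — the subset of chosen with both pre- and post-stress
  reports, adding rating, liked, improved and stress reduction.

Scalings match the published analysis: attention signals divided by 2000,
nudge probability multiplied by 100 (percent).  Chat messages are built
but left out of the default model formulas (the nudges were delivered
over the same chat channel, so the count is contaminated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .engine import FlowState
from .events import Event
from .profiles import TRAIT_NAMES, ParticipantProfile

logger = logging.getLogger(__name__)


class IntegrityError(ValueError):
    """The event log references nudges or windows that do not exist."""


@dataclass
class ContextWindow:
    """Half-hour telemetry aggregate, half-open [slot_start, +30 min)."""

    slot_start: datetime
    meeting_counts: int = 0
    no_meeting_minutes: float = 0.0
    self_event_counts: int = 0
    email_messages_sent: int = 0
    email_messages_read: int = 0
    chat_messages_count: int = 0
    ad_hoc_call_count: int = 0
    number_of_attention_signals: int = 0

    def __post_init__(self) -> None:
        for name in (
            "meeting_counts", "self_event_counts", "email_messages_sent",
            "email_messages_read", "chat_messages_count", "ad_hoc_call_count",
            "number_of_attention_signals",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_payload(self) -> dict:
        return {
            "slot_start": self.slot_start.strftime("%Y-%m-%dT%H:%M:%S"),
            "meeting_counts": int(self.meeting_counts),
            "no_meeting_minutes": float(self.no_meeting_minutes),
            "self_event_counts": int(self.self_event_counts),
            "email_messages_sent": int(self.email_messages_sent),
            "email_messages_read": int(self.email_messages_read),
            "chat_messages_count": int(self.chat_messages_count),
            "ad_hoc_call_count": int(self.ad_hoc_call_count),
            "number_of_attention_signals": int(self.number_of_attention_signals),
        }


def assign_half_hour(ts: datetime) -> datetime:
    """Largest :00/:30 boundary <= ts (half-open window convention)."""
    return ts.replace(minute=ts.minute - ts.minute % 30, second=0, microsecond=0)


def engagement_skewness(engagement_hours: Iterable[float]) -> float:
    """Fisher-Pearson coefficient of skewness g1 = m3 / m2^(3/2) of the
    hour-of-day values at which a participant engaged.

    Positive values mean engagement concentrated early in the workday.
    Fewer than 3 values, or zero variance, yield 0 (with a logged
    warning) so every participant remains usable as a covariate row.
    """
    hours = np.asarray(list(engagement_hours), dtype=float)
    if hours.size < 3:
        logger.warning(
            "engagement skewness undefined for %d value(s); using 0", hours.size
        )
        return 0.0
    centered = hours - hours.mean()
    m2 = np.mean(centered**2)
    # scale-relative zero-variance guard (also catches float underflow)
    if m2 <= 1e-24 * max(1.0, float(np.abs(hours).max()) ** 2):
        logger.warning("engagement skewness undefined for zero variance; using 0")
        return 0.0
    g1 = float(np.mean(centered**3) / m2**1.5)
    return g1 if np.isfinite(g1) else 0.0


def nudge_probability(
    all_nudge_slots_for_participant: Iterable[time], query_slot: time
) -> float:
    """Participant's empirical share of nudges in a half-hour-of-day slot,
    in percent."""
    slots = list(all_nudge_slots_for_participant)
    if not slots:
        raise ValueError("nudge probability undefined for an empty slot list")
    return 100.0 * sum(1 for s in slots if s == query_slot) / len(slots)


def label_outcomes(flow: FlowState) -> dict:
    """Outcome labels for one nudge's flow.

    ``engaged`` is True iff "done" was reached; ``liked`` iff the rating
    was good/very good (>= 4 of 5); ``improved`` iff the post-stress
    report is below the pre-stress report.  Labels whose inputs were
    never submitted are ``None`` (absent), not False.
    """
    if flow.state == "idle" and not flow.history:
        raise ValueError("flow never reached the nudged state")
    if flow.rating is not None and not 1 <= flow.rating <= 5:
        raise ValueError(f"rating {flow.rating} outside the 1-5 scale")
    engaged = flow.engaged
    liked = None if flow.rating is None else bool(flow.rating >= 4)
    improved = None
    reduction = None
    if flow.pre_stress is not None and flow.post_stress is not None:
        improved = bool(flow.post_stress < flow.pre_stress)
        reduction = flow.pre_stress - flow.post_stress
    return {
        "engaged": engaged,
        "liked": liked,
        "improved": improved,
        "stress_reduction": reduction,
    }


_FLOW_EVENT_TYPES = frozenset(
    {
        "nudge_postponed", "nudge_expired", "category_chosen",
        "pre_stress_reported", "intervention_assigned", "intervention_done",
        "intervention_rated", "post_stress_reported", "flow_abandoned",
    }
)


def build_model_tables(
    events: Iterable[Event], window_minutes: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build (per_nudge, chosen, completed) analysis tables from a log.

    Raises :class:`IntegrityError` for flow events whose nudge_id has no
    nudge_sent event, or nudges with no covering context window.
    """
    profiles: dict[str, ParticipantProfile] = {}
    windows: dict[tuple[str, datetime], dict] = {}
    nudges: dict[str, dict] = {}
    order: list[str] = []
    orphans: list[str] = []

    for ev in events:
        pid = ev.participant_id
        if ev.event_type == "participant_enrolled":
            profiles[pid] = ParticipantProfile.from_dict(ev.payload)
        elif ev.event_type == "context_window":
            slot = datetime.strptime(ev.payload["slot_start"], "%Y-%m-%dT%H:%M:%S")
            windows[(pid, slot)] = ev.payload
        elif ev.event_type == "nudge_sent":
            nid = ev.payload["nudge_id"]
            nudges[nid] = {
                "participant_id": pid,
                "nudge_id": nid,
                "timestamp": ev.timestamp,
                "trigger_source": (
                    "rescheduled" if ev.payload.get("source") == "rescheduled" else "system"
                ),
                "ema_at_nudge": ev.payload.get("latest_ema"),
                "flow": {"done_time": None, "category": None, "modality": None,
                         "location": None, "pre": None, "post": None,
                         "rating": None, "engaged": False},
            }
            order.append(nid)
        elif ev.event_type in _FLOW_EVENT_TYPES:
            nid = ev.payload.get("nudge_id")
            if nid not in nudges:
                orphans.append(f"{ev.event_type}:{nid}")
                continue
            flow = nudges[nid]["flow"]
            if ev.event_type == "category_chosen":
                flow["category"] = ev.payload["category"]
            elif ev.event_type == "intervention_assigned":
                flow["modality"] = ev.payload["modality"]
                flow["location"] = ev.payload["location"]
            elif ev.event_type == "pre_stress_reported":
                flow["pre"] = int(ev.payload["value"])
            elif ev.event_type == "intervention_done":
                flow["engaged"] = True
                flow["done_time"] = ev.timestamp
            elif ev.event_type == "intervention_rated":
                flow["rating"] = int(ev.payload["value"])
            elif ev.event_type == "post_stress_reported":
                flow["post"] = int(ev.payload["value"])

    if orphans:
        raise IntegrityError(
            f"flow events without a matching nudge: {sorted(set(orphans))}"
        )

    # Per-participant derived features.
    skew: dict[str, float] = {}
    slots_by_pid: dict[str, list[time]] = {}
    for nid in order:
        rec = nudges[nid]
        slots_by_pid.setdefault(rec["participant_id"], []).append(
            assign_half_hour(rec["timestamp"]).time()
        )
    for pid in profiles:
        hours = [
            rec["flow"]["done_time"].hour + rec["flow"]["done_time"].minute / 60.0
            for rec in nudges.values()
            if rec["participant_id"] == pid and rec["flow"]["done_time"] is not None
        ]
        skew[pid] = engagement_skewness(hours)

    rows = []
    for nid in order:
        rec = nudges[nid]
        pid = rec["participant_id"]
        profile = profiles.get(pid)
        if profile is None:
            raise IntegrityError(f"nudge {nid} for unknown participant {pid}")
        slot = assign_half_hour(rec["timestamp"])
        win = windows.get((pid, slot))
        if win is None:
            raise IntegrityError(f"nudge {nid} has no context window at {slot}")
        flow = rec["flow"]
        nmm = float(win["no_meeting_minutes"])
        if nmm > window_minutes:
            logger.warning(
                "no_meeting_minutes %.1f exceeds the %d-min window; capping",
                nmm, window_minutes,
            )
            nmm = float(window_minutes)
        row = {
            "participant_id": pid,
            "nudge_id": nid,
            "timestamp": rec["timestamp"],
            "age_group": profile.age_group,
            "gender": profile.gender,
            **{t: profile.traits[t] for t in TRAIT_NAMES},
            "engagement_skewness": skew[pid],
            "nudge_probability": nudge_probability(slots_by_pid[pid], slot.time()),
            "meeting_counts": int(win["meeting_counts"]),
            "no_meeting_minutes": nmm,
            "self_event_counts": int(win["self_event_counts"]),
            "email_messages_sent": int(win["email_messages_sent"]),
            "email_messages_read": int(win["email_messages_read"]),
            "chat_messages_count": int(win["chat_messages_count"]),
            "ad_hoc_call_count": int(win["ad_hoc_call_count"]),
            "attention_signals": float(win["number_of_attention_signals"]) / 2000.0,
            "trigger_source": rec["trigger_source"],
            "ema_at_nudge": rec["ema_at_nudge"],
            "engaged": bool(flow["engaged"]),
            "category": flow["category"],
            "modality": flow["modality"],
            "location": flow["location"],
            "stress_before": flow["pre"],
            "stress_after": flow["post"],
            "rating": flow["rating"],
        }
        row["liked"] = None if flow["rating"] is None else bool(flow["rating"] >= 4)
        if flow["pre"] is not None and flow["post"] is not None:
            row["improved"] = bool(flow["post"] < flow["pre"])
            row["stress_reduction"] = flow["pre"] - flow["post"]
        else:
            row["improved"] = None
            row["stress_reduction"] = None
        rows.append(row)

    per_nudge = pd.DataFrame(rows)
    if per_nudge.empty:
        return per_nudge, per_nudge.copy(), per_nudge.copy()
    chosen = per_nudge[per_nudge["category"].notna()].reset_index(drop=True)
    completed = chosen[
        chosen["stress_before"].notna() & chosen["stress_after"].notna()
    ].reset_index(drop=True)
    return per_nudge, chosen, completed


def write_tables(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame], outdir
) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in zip(("per_nudge", "chosen", "completed"), tables):
        df.to_csv(outdir / f"{name}.csv", index=False)


def read_tables(outdir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    from pathlib import Path

    outdir = Path(outdir)
    out = []
    for name in ("per_nudge", "chosen", "completed"):
        df = pd.read_csv(outdir / f"{name}.csv", parse_dates=["timestamp"])
        out.append(df)
    return tuple(out)
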