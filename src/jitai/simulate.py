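"""Event-driven deployment simulator.

Simulates a cohort of information workers through a multi-week
deployment of the just-in-time stress-intervention system: per-day
half-hour telemetry aggregates and continuous sensed streams, five EMA
prompts per workday, the 5-minute heuristic tick with the full nudge
gate, and nudge-response behaviour drawn from the truth models.  The
output is a time-ordered JSONL-able event log that satisfies every
gating invariant of the engine by construction — and can be *replayed*
through the engine (:func:`replay_decisions`) to prove it.

Determinism: one global seed fans out into per-participant substreams,
so changing the cohort size never reshuffles existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np

from .catalog import Intervention, default_catalog
from .config import ConfigurationError, SimulationConfig
from .engine import (
    DEFAULT_BASELINE,
    Baseline,
    GateDecision,
    SchedulingState,
    SensedSample,
    StressScore,
    compute_stress_score,
    gate_nudge,
    learn_baseline,
    schedule_emas,
    select_intervention,
)
from .events import Event, sort_events
from .features import ContextWindow, assign_half_hour
from .profiles import ParticipantProfile, TRAIT_NAMES, generate_participants
from .truth import TruthModels, simulate_response

STUDY_START = date(2024, 1, 1)  # a Monday; weekdays only are simulated


def workdays(start: date, weeks: int) -> list[date]:
    return [
        start + timedelta(weeks=w, days=d) for w in range(weeks) for d in range(5)
    ]


def generate_context_day(
    profile: ParticipantProfile,
    day: date,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> tuple[list[ContextWindow], list[SensedSample]]:
    """One workday of half-hour telemetry windows plus per-tick sensed
    samples (cumulative email/meeting counts, day-fraction ramp, AR(1)
    facial score and heart rate)."""
    cfg = config or SimulationConfig()
    cx, eng = cfg.context, cfg.engine
    start = datetime.combine(day, profile.work_start)
    end = datetime.combine(day, profile.work_end)
    total_min = int((end - start).total_seconds() // 60)
    n_windows = max(1, total_min // cx.window_minutes)
    ticks_per_window = max(1, cx.window_minutes // eng.tick_minutes)

    # Mean-one lognormal day effect: busy and light days average out, so
    # unconditional window means stay at the configured rates.
    load = profile.load_multiplier * float(
        np.exp(rng.normal(0.0, cx.day_load_sd) - cx.day_load_sd**2 / 2)
    )

    def nb(mean, disp, size):
        m = mean * load
        if m <= 0 or disp <= 0:
            return np.zeros(size, dtype=int)
        return rng.negative_binomial(disp, disp / (disp + m), size=size)

    meetings = rng.poisson(cx.meetings_mean * load, n_windows)
    windows = []
    emails_received = nb(cx.emails_received_mean, cx.emails_received_disp, n_windows)
    for i in range(n_windows):
        slot = start + timedelta(minutes=i * cx.window_minutes)
        nmm = 0.0
        if rng.random() < cx.no_meeting_p_nonzero and cx.no_meeting_scale > 0:
            nmm = float(min(rng.exponential(cx.no_meeting_scale), cx.window_minutes))
        windows.append(
            ContextWindow(
                slot_start=slot,
                meeting_counts=int(meetings[i]),
                no_meeting_minutes=nmm,
                self_event_counts=int(rng.poisson(cx.self_events_mean * load)),
                email_messages_sent=int(nb(cx.emails_sent_mean, cx.emails_sent_disp, 1)[0]),
                email_messages_read=int(nb(cx.emails_read_mean, cx.emails_read_disp, 1)[0]),
                chat_messages_count=int(nb(cx.chats_mean, cx.chats_disp, 1)[0]),
                ad_hoc_call_count=int(rng.poisson(cx.adhoc_calls_mean * load)),
                number_of_attention_signals=int(
                    min(nb(cx.attention_mean, cx.attention_disp, 1)[0], cx.attention_cap)
                ),
            )
        )

    # Continuous streams at engine ticks.
    n_ticks = total_min // eng.tick_minutes
    facial = 0.0
    hr = profile.hr_mean
    samples = []
    for t in range(n_ticks):
        now = start + timedelta(minutes=t * eng.tick_minutes)
        w = min(t // ticks_per_window, n_windows - 1)
        frac_window = (t % ticks_per_window + 1) / ticks_per_window
        cum_emails = float(emails_received[:w].sum() + frac_window * emails_received[w])
        cum_meetings = float(meetings[:w].sum() + frac_window * meetings[w])
        facial = cx.facial_ar * facial + rng.normal(
            0.0, cx.facial_sd * np.sqrt(max(1e-12, 1 - cx.facial_ar**2))
        )
        facial = float(np.clip(facial, -cx.facial_cap, cx.facial_cap))
        hr = (
            cx.heart_rate_ar * hr
            + (1 - cx.heart_rate_ar) * profile.hr_mean
            + rng.normal(0.0, cx.heart_rate_within_sd)
        )
        samples.append(
            SensedSample(
                timestamp=now,
                emails_received_running=cum_emails,
                meetings_today=cum_meetings,
                fraction_of_day=(t + 1) * eng.tick_minutes / total_min,
                facial_score=facial,
                heart_rate=max(40.0, float(hr)),
                attention_events=int(
                    windows[w].number_of_attention_signals / ticks_per_window
                ),
            )
        )
    return windows, samples


@dataclass
class _ParticipantState:
    profile: ParticipantProfile
    rng: np.random.Generator
    sched: SchedulingState = None  # rebuilt each day with that day's hours
    baseline: Baseline = DEFAULT_BASELINE
    nudge_times: list = None
    completion_times: list = None
    served: set = None
    week1_scores: list = None
    week1_emas: list = None
    nudge_counter: int = 0
    latent_nudge_prob: float = 6.0

    def __post_init__(self):
        self.nudge_times = []
        self.completion_times = []
        self.served = set()
        self.week1_scores = []
        self.week1_emas = []
        self.latent_nudge_prob = float(
            np.clip(self.rng.gamma(2.25, 6.0 / 2.25), 2.0, 30.0)
        )


def _nudge_record(
    ps: _ParticipantState, window: ContextWindow, source: str
) -> dict:
    p = ps.profile
    rec = {t: p.traits[t] for t in TRAIT_NAMES}
    rec.update(
        age_group=p.age_group,
        gender=p.gender,
        engagement_skewness=p.latent_skewness,
        nudge_probability=ps.latent_nudge_prob,
        meeting_counts=window.meeting_counts,
        no_meeting_minutes=window.no_meeting_minutes,
        self_event_counts=window.self_event_counts,
        email_messages_sent=window.email_messages_sent,
        email_messages_read=window.email_messages_read,
        chat_messages_count=window.chat_messages_count,
        ad_hoc_call_count=window.ad_hoc_call_count,
        attention_signals=window.number_of_attention_signals / 2000.0,
        trigger_source="rescheduled" if source == "rescheduled" else "system",
    )
    return rec


def run_deployment(
    cohort: list[ParticipantProfile] | None = None,
    truth: TruthModels | None = None,
    weeks: int | None = None,
    seed: int = 0,
    config: SimulationConfig | None = None,
    catalog: list[Intervention] | None = None,
) -> list[Event]:
    """Simulate the full deployment and return the global event log.

    ``weeks`` must be >= 2: week 1 runs on default baselines and its data
    learn the individualized baselines used in the remaining weeks.
    """
    cfg = config or SimulationConfig()
    if weeks is not None:
        cfg.weeks = weeks
    cfg.validate()
    if cfg.weeks < 2:  # validate() also checks; explicit for direct calls
        raise ConfigurationError("weeks must be >= 2")
    truth = truth or TruthModels()
    catalog = catalog or default_catalog()
    if cohort is None:
        cohort = generate_participants(cfg.cohort.n_participants, cfg.cohort, seed)

    events: list[Event] = []
    days = workdays(STUDY_START, cfg.weeks)
    eng = cfg.engine

    for idx, profile in enumerate(cohort):
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx, 101)))
        ps = _ParticipantState(profile=profile, rng=rng)
        pid = profile.participant_id
        events.append(
            Event(
                datetime.combine(days[0], profile.work_start),
                pid,
                "participant_enrolled",
                profile.to_dict(),
            )
        )

        def select(category: str) -> Intervention:
            return select_intervention(category, ps.served, ps.rng, catalog)

        for day_i, day in enumerate(days):
            week = day_i // 5
            if week == 1 and day_i % 5 == 0:
                ps.baseline = learn_baseline(ps.week1_scores, ps.week1_emas)
            start = datetime.combine(day, profile.work_start)
            end = datetime.combine(day, profile.work_end)
            windows, samples = generate_context_day(profile, day, rng, cfg)
            for w in windows:
                events.append(Event(w.slot_start, pid, "context_window", w.to_payload()))
            ema_times = schedule_emas(
                start, end, rng, eng.emas_per_day, eng.ema_min_spacing_min
            )
            ema_i = 0
            latest_ema: Optional[tuple[int, datetime]] = None
            pending: Optional[datetime] = None
            ps.sched = SchedulingState(
                work_start=start,
                work_end=end,
                nudge_times=ps.nudge_times,
                completion_times=ps.completion_times,
            )

            for sample in samples:
                now = sample.timestamp
                score = compute_stress_score(sample, eng.normalizers)
                if week == 0:
                    ps.week1_scores.append(score.value)
                if cfg.log_scores:
                    events.append(
                        Event(now, pid, "stress_score", {"value": round(score.value, 4)})
                    )
                # EMA prompts due by this tick.
                while ema_i < len(ema_times) and ema_times[ema_i] <= now:
                    t_ema = ema_times[ema_i]
                    lam = max(
                        0.0,
                        cfg.context.ema_rate_base
                        + cfg.context.ema_rate_slope * score.value,
                    )
                    val = int(min(5, 1 + rng.poisson(lam)))
                    events.append(Event(t_ema, pid, "ema_prompt", {}))
                    events.append(Event(t_ema, pid, "ema_response", {"value": val}))
                    latest_ema = (val, t_ema)
                    if week == 0:
                        ps.week1_emas.append(val)
                    ema_i += 1

                fresh_ema = None
                if latest_ema is not None and now - latest_ema[1] <= timedelta(
                    minutes=eng.ema_freshness_min
                ):
                    fresh_ema = latest_ema[0]

                ps.sched.pending_reschedule = pending
                if pending is not None:
                    if now >= pending:
                        decision = gate_nudge(
                            ps.sched, now, score, fresh_ema, ps.baseline, eng,
                            is_rescheduled=True,
                        )
                        if decision.send:
                            pending = None
                            _send_nudge(
                                ps, events, now, score, fresh_ema, "rescheduled",
                                windows, start, truth, select, end, cfg,
                            )
                    continue  # no JIT nudge while a reschedule is pending

                decision = gate_nudge(
                    ps.sched, now, score, fresh_ema, ps.baseline, eng
                )
                if decision.send:
                    pending = _send_nudge(
                        ps, events, now, score, fresh_ema, "JIT",
                        windows, start, truth, select, end, cfg,
                    )
            # EMAs scheduled after the last tick still get answered.
            while ema_i < len(ema_times):
                t_ema = ema_times[ema_i]
                lam = max(
                    0.0,
                    cfg.context.ema_rate_base
                    + cfg.context.ema_rate_slope * score.value,
                )
                val = int(min(5, 1 + rng.poisson(lam)))
                events.append(Event(t_ema, pid, "ema_prompt", {}))
                events.append(Event(t_ema, pid, "ema_response", {"value": val}))
                if week == 0:
                    ps.week1_emas.append(val)
                ema_i += 1
            # A postponement whose time never cleared the gates lapses at
            # the end of the day.

    return sort_events(events)


def _send_nudge(
    ps: _ParticipantState,
    events: list[Event],
    now: datetime,
    score: StressScore,
    fresh_ema: Optional[int],
    source: str,
    windows: list[ContextWindow],
    day_start: datetime,
    truth: TruthModels,
    select,
    work_end: datetime,
    cfg: SimulationConfig,
) -> Optional[datetime]:
    """Emit a nudge and its simulated behavioural follow-up events.
    Returns the postponed-until time if the user rescheduled, else None."""
    pid = ps.profile.participant_id
    rng = ps.rng
    nid = f"{pid}-n{ps.nudge_counter:04d}"
    ps.nudge_counter += 1
    slot = assign_half_hour(now)
    w_idx = min(
        int((slot - day_start).total_seconds() // (cfg.context.window_minutes * 60)),
        len(windows) - 1,
    )
    window = windows[w_idx]
    events.append(
        Event(
            now, pid, "nudge_sent",
            {
                "nudge_id": nid,
                "source": source,
                # full precision: the replay oracle re-evaluates the trigger
                "score": score.value,
                "score_threshold": ps.baseline.score_threshold,
                "ema_threshold": ps.baseline.ema_threshold,
                "latest_ema": fresh_ema,
                "slot_start": slot.strftime("%Y-%m-%dT%H:%M:%S"),
            },
        )
    )
    ps.nudge_times.append(now)

    record = _nudge_record(ps, window, source)
    outcome = simulate_response(record, ps.profile, truth, rng, select=select)

    if outcome.action == "postpone":
        remaining = (work_end - now).total_seconds()
        if remaining < 15 * 60:  # too late to reschedule; user lets it lapse
            events.append(
                Event(now + timedelta(minutes=cfg.engine.nudge_expiry_min), pid,
                      "nudge_expired", {"nudge_id": nid})
            )
            return None
        until = now + timedelta(seconds=float(rng.uniform(10 * 60, remaining)))
        events.append(
            Event(
                now + timedelta(minutes=float(rng.uniform(1, 5))), pid,
                "nudge_postponed",
                {"nudge_id": nid, "until": until.strftime("%Y-%m-%dT%H:%M:%S")},
            )
        )
        return until

    if outcome.action == "ignore":
        events.append(
            Event(now + timedelta(minutes=cfg.engine.nudge_expiry_min), pid,
                  "nudge_expired", {"nudge_id": nid})
        )
        return None

    lat = timedelta(minutes=float(rng.uniform(1, 25)))
    t = now + lat
    events.append(
        Event(t, pid, "category_chosen", {"nudge_id": nid, "category": outcome.category})
    )
    item = outcome.intervention
    events.append(
        Event(
            t, pid, "intervention_assigned",
            {
                "nudge_id": nid,
                "intervention_id": item.intervention_id,
                "category": item.category,
                "modality": item.modality,
                "location": item.location,
            },
        )
    )
    t += timedelta(minutes=1)
    events.append(
        Event(t, pid, "pre_stress_reported", {"nudge_id": nid, "value": outcome.pre_stress})
    )
    if outcome.action == "choose_abandon":
        events.append(
            Event(t + timedelta(minutes=2), pid, "flow_abandoned", {"nudge_id": nid})
        )
        return None

    t += timedelta(minutes=float(rng.uniform(2, 5)))
    events.append(Event(t, pid, "intervention_done", {"nudge_id": nid}))
    ps.completion_times.append(t)
    if outcome.completed:
        t += timedelta(minutes=1)
        events.append(
            Event(t, pid, "intervention_rated", {"nudge_id": nid, "value": outcome.rating})
        )
        t += timedelta(minutes=1)
        events.append(
            Event(
                t, pid, "post_stress_reported",
                {"nudge_id": nid, "value": outcome.post_stress},
            )
        )
    return None


# ---------------------------------------------------------------------------
# Engine replay
# ---------------------------------------------------------------------------

def replay_decisions(
    events: list[Event], config: SimulationConfig | None = None
) -> list[GateDecision]:
    """Re-evaluate the nudge gate at every logged nudge from the log's own
    history and return the decisions (all of which must be sends for a
    log produced by :func:`run_deployment`)."""
    cfg = config or SimulationConfig()
    eng = cfg.engine
    profiles: dict[str, ParticipantProfile] = {}
    hist: dict[str, SchedulingState] = {}
    pending: dict[str, Optional[datetime]] = {}
    pending_day: dict[str, Optional[date]] = {}
    decisions = []

    for ev in events:
        pid = ev.participant_id
        if ev.event_type == "participant_enrolled":
            profiles[pid] = ParticipantProfile.from_dict(ev.payload)
            hist[pid] = SchedulingState(
                work_start=ev.timestamp, work_end=ev.timestamp
            )
            pending[pid] = None
            pending_day[pid] = None
        elif ev.event_type == "nudge_postponed":
            pending[pid] = datetime.strptime(
                ev.payload["until"], "%Y-%m-%dT%H:%M:%S"
            )
            pending_day[pid] = ev.timestamp.date()
        elif ev.event_type == "intervention_done":
            hist[pid].completion_times.append(ev.timestamp)
        elif ev.event_type == "nudge_sent":
            profile = profiles[pid]
            state = hist[pid]
            state.work_start = datetime.combine(ev.timestamp.date(), profile.work_start)
            state.work_end = datetime.combine(ev.timestamp.date(), profile.work_end)
            if pending_day[pid] is not None and pending_day[pid] != ev.timestamp.date():
                pending[pid] = None  # unfired postponements lapse overnight
                pending_day[pid] = None
            is_res = ev.payload.get("source") == "rescheduled"
            state.pending_reschedule = None if is_res else pending[pid]
            score = StressScore(float(ev.payload["score"]), {})
            baseline = Baseline(
                float(ev.payload["score_threshold"]),
                float(ev.payload["ema_threshold"]),
            )
            decision = gate_nudge(
                state, ev.timestamp, score, ev.payload.get("latest_ema"),
                baseline, eng, is_rescheduled=is_res,
            )
            decisions.append(decision)
            state.nudge_times.append(ev.timestamp)
            if is_res:
                pending[pid] = None
                pending_day[pid] = None
    return decisions
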