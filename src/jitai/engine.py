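"""The just-in-time decision engine.

This module implements the deterministic heart of the intervention
system:

* a composite **stress score** — the arithmetic mean of five normalized
  components (emails received today, meetings today, fraction of the
  workday elapsed, facial-expression score, heart rate), each clipped to
  [0, 1];
* **individualized baselines** — week-1 averages of the computed score
  and of the self-reported EMA stress ratings, defaulting to the
  midpoints of their ranges (0.5 and 3) until learned;
* the **nudge gate** — a nudge is sent only during the participant's
  stated working hours, with no user-scheduled intervention pending later
  that day, no intervention completed in the past hour, no nudge in the
  past two hours, fewer than four nudges that day, and the stress trigger
  firing (score above its baseline or a fresh EMA above its baseline);
* **EMA scheduling** — five prompts per workday at random, minimally
  spaced times within working hours;
* the **engagement-flow state machine** — nudge → (postpone | expire |
  choose category → report pre-stress → intervention → done → rate →
  report post-stress), where "done" marks the flow engaged regardless of
  any subsequent prompts;
* uniform **intervention selection** without replacement within a
  category, resetting once the 18-item category is exhausted.

The engine is evaluated on a fixed tick (5 minutes by default) aligned to
the start of the workday and never emits a nudge off-tick.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

import numpy as np

from .catalog import CATEGORIES, Intervention
from .config import ConfigurationError, EngineConfig, NormalizerConfig

COMPONENT_NAMES = (
    "emails_received",
    "meetings_today",
    "fraction_of_day",
    "facial",
    "heart_rate",
)


class MissingComponentError(ValueError):
    """A stress-score component required by the normalizer set is absent."""


class FlowError(RuntimeError):
    """An event was applied to a flow state where it is not legal."""


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sensed samples and the composite stress score
# ---------------------------------------------------------------------------

@dataclass
class SensedSample:
    """One engine-tick snapshot of the continuously sensed signals."""

    timestamp: datetime
    emails_received_running: float  # emails received so far today
    meetings_today: float  # meetings so far today
    fraction_of_day: float  # proportion of the workday elapsed, in [0, 1]
    facial_score: float  # corrugator + lip depressor - zygomatic
    heart_rate: float  # beats/min
    attention_events: int = 0  # mouse/keyboard events this interval

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_day <= 1.0:
            raise ValidationError(
                f"fraction_of_day {self.fraction_of_day} outside [0, 1]"
            )
        if self.emails_received_running < 0 or self.meetings_today < 0:
            raise ValidationError("counts must be >= 0")
        if self.heart_rate <= 0:
            raise ValidationError("heart_rate must be > 0")


@dataclass(frozen=True)
class StressScore:
    value: float
    components: dict[str, float]


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def compute_stress_score(
    sample: SensedSample, normalizers: NormalizerConfig | None = None
) -> StressScore:
    """Average of the five normalized stress components.

    Each component is min-max normalized with the configured floors/caps
    and clipped to [0, 1]; the composite is their arithmetic mean.
    """
    nz = normalizers or NormalizerConfig()
    raw = {
        "emails_received": sample.emails_received_running,
        "meetings_today": sample.meetings_today,
        "fraction_of_day": sample.fraction_of_day,
        "facial": sample.facial_score,
        "heart_rate": sample.heart_rate,
    }
    for name in COMPONENT_NAMES:
        if raw[name] is None:
            raise MissingComponentError(f"stress component {name!r} is missing")
    components = {
        "emails_received": _clip01(
            (raw["emails_received"] - nz.emails_lo) / (nz.emails_hi - nz.emails_lo)
        ),
        "meetings_today": _clip01(
            (raw["meetings_today"] - nz.meetings_lo) / (nz.meetings_hi - nz.meetings_lo)
        ),
        "fraction_of_day": _clip01(raw["fraction_of_day"]),
        "facial": _clip01(
            (raw["facial"] + nz.facial_cap) / (2.0 * nz.facial_cap)
        ),
        "heart_rate": _clip01(
            (raw["heart_rate"] - nz.heart_rate_lo)
            / (nz.heart_rate_hi - nz.heart_rate_lo)
        ),
    }
    value = sum(components[n] for n in COMPONENT_NAMES) / len(COMPONENT_NAMES)
    return StressScore(value=value, components=components)


# ---------------------------------------------------------------------------
# Individualized baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Baseline:
    score_threshold: float  # in [0, 1]
    ema_threshold: float  # in [1, 5]
    score_source: str = "default"  # "default" | "learned"
    ema_source: str = "default"

    @property
    def source(self) -> str:
        return (
            "learned"
            if "learned" in (self.score_source, self.ema_source)
            else "default"
        )


DEFAULT_BASELINE = Baseline(0.5, 3.0)


def learn_baseline(
    week1_scores: Iterable[float], week1_emas: Iterable[int]
) -> Baseline:
    """Week-1 averages of computed scores and EMA ratings; empty inputs
    fall back to the midpoints of the respective ranges."""
    scores = list(week1_scores)
    emas = list(week1_emas)
    for e in emas:
        if not 1 <= e <= 5:
            raise ValidationError(f"EMA value {e} outside the 1-5 scale")
    score_thr, score_src = (float(np.mean(scores)), "learned") if scores else (0.5, "default")
    ema_thr, ema_src = (float(np.mean(emas)), "learned") if emas else (3.0, "default")
    return Baseline(score_thr, ema_thr, score_src, ema_src)


# ---------------------------------------------------------------------------
# The nudge gate
# ---------------------------------------------------------------------------

@dataclass
class SchedulingState:
    """Time-ordered per-participant scheduling history used by the gate."""

    work_start: datetime
    work_end: datetime
    nudge_times: list[datetime] = field(default_factory=list)  # all sent nudges
    completion_times: list[datetime] = field(default_factory=list)
    pending_reschedule: Optional[datetime] = None  # user-scheduled, later today

    def validate(self) -> None:
        for seq, name in ((self.nudge_times, "nudge_times"),
                          (self.completion_times, "completion_times")):
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValidationError(f"{name} is not time-ordered")

    def nudges_today(self, now: datetime) -> list[datetime]:
        return [t for t in self.nudge_times if t.date() == now.date()]


@dataclass(frozen=True)
class GateDecision:
    send: bool
    reason: Optional[str] = None  # first failing rule, in rule order

    def __bool__(self) -> bool:
        return self.send


def _trigger_fires(
    stress: StressScore,
    latest_ema: Optional[int],
    baseline: Baseline,
    mode: str,
) -> bool:
    score_hit = stress.value > baseline.score_threshold
    ema_hit = latest_ema is not None and latest_ema > baseline.ema_threshold
    if mode == "or":
        return score_hit or ema_hit
    if mode == "and":
        return score_hit and ema_hit
    if mode == "score":
        return score_hit
    return ema_hit


def gate_nudge(
    state: SchedulingState,
    now: datetime,
    stress: StressScore,
    latest_ema: Optional[int],
    baseline: Baseline,
    config: EngineConfig | None = None,
    *,
    is_rescheduled: bool = False,
) -> GateDecision:
    """Decide whether a nudge may be sent at ``now``.

    The five scheduling rules are checked in order and the block carries
    the first failing reason: working hours, pending user-scheduled
    intervention, 60-minute post-completion cooldown, 120-minute nudge
    cooldown, 4-per-day cap, and finally the stress trigger.  A nudge
    firing at its user-rescheduled time (``is_rescheduled``) skips the
    pending-reschedule rule and the trigger but still honours the
    cooldowns and the daily cap.
    """
    cfg = config or EngineConfig()
    state.validate()
    if latest_ema is not None and not 1 <= latest_ema <= 5:
        raise ValidationError(f"EMA value {latest_ema} outside the 1-5 scale")

    # (i) working hours, half-open [start, end)
    if not (state.work_start <= now < state.work_end):
        return GateDecision(False, "outside_working_hours")
    # (ii) a user-scheduled intervention is pending later today
    if (
        not is_rescheduled
        and state.pending_reschedule is not None
        and state.pending_reschedule.date() == now.date()
        and state.pending_reschedule > now
    ):
        return GateDecision(False, "pending_reschedule")
    # (iii) an intervention was completed in the past hour
    if any(
        timedelta(0) <= now - t < timedelta(minutes=cfg.completion_cooldown_min)
        for t in state.completion_times
    ):
        return GateDecision(False, "completion_cooldown")
    # (iv) a nudge was sent in the past two hours
    if any(
        timedelta(0) <= now - t < timedelta(minutes=cfg.nudge_cooldown_min)
        for t in state.nudge_times
    ):
        return GateDecision(False, "nudge_cooldown")
    # (v) fewer than 4 nudges today
    if len(state.nudges_today(now)) >= cfg.daily_nudge_cap:
        return GateDecision(False, "daily_cap")
    # (vi) the stress trigger
    if not is_rescheduled and not _trigger_fires(
        stress, latest_ema, baseline, cfg.trigger_mode
    ):
        return GateDecision(False, "no_trigger")
    return GateDecision(True)


# ---------------------------------------------------------------------------
# EMA scheduling
# ---------------------------------------------------------------------------

def schedule_emas(
    work_start: datetime,
    work_end: datetime,
    rng: np.random.Generator,
    n_emas: int = 5,
    min_spacing_min: int = 45,
) -> list[datetime]:
    """Draw ``n_emas`` strictly increasing prompt times in
    [work_start, work_end) with a minimum spacing, uniformly via the
    gap construction."""
    total = (work_end - work_start).total_seconds()
    if total <= 0:
        raise ConfigurationError("empty workday")
    spacing = min_spacing_min * 60.0
    slack = total - (n_emas - 1) * spacing
    if slack <= 0:
        raise ConfigurationError(
            f"workday of {total / 60:.0f} min cannot hold {n_emas} EMAs "
            f"spaced >= {min_spacing_min} min"
        )
    offsets = np.sort(rng.uniform(0.0, slack, size=n_emas))
    return [
        work_start + timedelta(seconds=float(off + i * spacing))
        for i, off in enumerate(offsets)
    ]


# ---------------------------------------------------------------------------
# Engagement-flow state machine
# ---------------------------------------------------------------------------

TERMINAL_STATES = frozenset({"expired", "abandoned", "post_stress_reported"})
ENGAGED_STATES = frozenset({"done", "rated", "post_stress_reported"})

# state -> {event: next_state}
_TRANSITIONS: dict[str, dict[str, str]] = {
    "idle": {"nudge": "nudged"},
    "nudged": {
        "postpone": "postponed",
        "choose_category": "category_chosen",
        "timeout": "expired",
    },
    "postponed": {},
    "category_chosen": {"report_pre_stress": "pre_stress_reported", "abandon": "abandoned"},
    "pre_stress_reported": {"begin": "intervention_active", "abandon": "abandoned"},
    "intervention_active": {"done": "done", "abandon": "abandoned"},
    "done": {"rate": "rated", "abandon": "abandoned"},
    "rated": {"report_post_stress": "post_stress_reported", "abandon": "abandoned"},
}


@dataclass
class FlowState:
    """State of one nudge's engagement flow, with its transition history."""

    state: str = "idle"
    nudge_source: str = "JIT"  # "JIT" | "rescheduled"
    nudge_id: Optional[str] = None
    nudge_time: Optional[datetime] = None
    postponed_until: Optional[datetime] = None
    postpone_count: int = 0
    category: Optional[str] = None
    intervention: Optional[Intervention] = None
    pre_stress: Optional[int] = None
    post_stress: Optional[int] = None
    rating: Optional[int] = None
    history: list[tuple[str, datetime]] = field(default_factory=list)

    @property
    def engaged(self) -> bool:
        """True once the intervention was explicitly marked done, regardless
        of whether the rating / post-stress prompts followed."""
        return self.state in ENGAGED_STATES or any(
            s in ENGAGED_STATES for s, _ in self.history
        )


def step_flow(
    flow: FlowState,
    event: str,
    now: datetime,
    payload: object = None,
    *,
    allow_repostpone: bool = False,
    expiry_min: int = 30,
) -> FlowState:
    """Apply one user/system event to a flow state and return the new state.

    Raises :class:`FlowError` for transitions outside the engagement-flow
    graph (e.g. rating before "done", or a second postponement when not
    allowed).
    """
    legal = _TRANSITIONS.get(flow.state, {})
    if event not in legal:
        raise FlowError(f"event {event!r} is illegal in state {flow.state!r}")

    new = dataclasses.replace(flow, history=list(flow.history) + [(flow.state, now)])
    new.state = legal[event]

    if event == "nudge":
        new.nudge_time = now
    elif event == "postpone":
        if flow.postpone_count >= 1 and not allow_repostpone:
            raise FlowError("nudge already postponed once")
        if not isinstance(payload, datetime) or payload <= now:
            raise FlowError("postpone requires a future datetime payload")
        new.postponed_until = payload
        new.postpone_count = flow.postpone_count + 1
    elif event == "timeout":
        if flow.nudge_time is not None and now - flow.nudge_time < timedelta(
            minutes=expiry_min
        ):
            raise FlowError(
                f"nudge expires only after {expiry_min} min of inactivity"
            )
    elif event == "choose_category":
        if payload not in CATEGORIES:
            raise FlowError(f"unknown category {payload!r}")
        new.category = payload
    elif event == "report_pre_stress":
        new.pre_stress = _check_rating(payload, "pre-stress")
    elif event == "begin":
        if isinstance(payload, Intervention):
            new.intervention = payload
    elif event == "rate":
        new.rating = _check_rating(payload, "rating")
    elif event == "report_post_stress":
        new.post_stress = _check_rating(payload, "post-stress")
    return new


def _check_rating(value: object, what: str) -> int:
    if not isinstance(value, (int, np.integer)) or not 1 <= int(value) <= 5:
        raise FlowError(f"{what} must be an integer on the 1-5 scale, got {value!r}")
    return int(value)


# ---------------------------------------------------------------------------
# Intervention selection
# ---------------------------------------------------------------------------

def select_intervention(
    category: str,
    served: set[str],
    rng: np.random.Generator,
    catalog: list[Intervention],
) -> Intervention:
    """Uniform draw over the category's catalog items not yet served to
    this participant; once the category is exhausted its served set is
    reset and all items become eligible again.  Mutates ``served``."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    pool = [it for it in catalog if it.category == category]
    if not pool:
        raise ConfigurationError(f"catalog has no items in category {category!r}")
    fresh = [it for it in pool if it.intervention_id not in served]
    if not fresh:
        for it in pool:
            served.discard(it.intervention_id)
        fresh = pool
    choice = fresh[int(rng.integers(len(fresh)))]
    served.add(choice.intervention_id)
    return choice
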