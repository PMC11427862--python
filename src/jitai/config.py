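"""Configuration objects for the simulator, engine and truth models.

Everything is a plain dataclass with defaults matching the deployment the
package emulates: 43 information workers observed for 4 weeks, 5 EMAs per
workday, half-hour workplace telemetry aggregates, and nudge-response
behaviour generated from published odds-ratio tables.  A YAML file with
sections ``cohort`` / ``context`` / ``engine`` / ``truth`` / top-level
``weeks`` and ``seed`` can override any field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import time
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its legal range."""


@dataclass
class TraitSpec:
    """Distribution of one psychometric trait: normal, clipped to the
    instrument range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ConfigurationError(
                f"trait {name!r}: mean {self.mean} outside instrument range "
                f"[{self.lo}, {self.hi}]"
            )
        if self.sd < 0:
            raise ConfigurationError(f"trait {name!r}: negative sd {self.sd}")


def _default_traits() -> dict[str, TraitSpec]:
    # Cohort descriptives: 1-7 emotion-regulation scales, 1-5 resilience and
    # Big Five scales.
    return {
        "cognitive_reappraisal": TraitSpec(4.69, 1.09, 1.0, 7.0),
        "expressive_suppression": TraitSpec(3.74, 1.26, 1.0, 7.0),
        "resilience": TraitSpec(3.51, 0.89, 1.0, 5.0),
        "agreeableness": TraitSpec(3.79, 0.74, 1.0, 5.0),
        "conscientiousness": TraitSpec(4.12, 0.83, 1.0, 5.0),
        "extraversion": TraitSpec(2.62, 0.86, 1.0, 5.0),
        "neuroticism": TraitSpec(2.85, 1.04, 1.0, 5.0),
        "openness": TraitSpec(3.48, 0.79, 1.0, 5.0),
    }


AGE_GROUPS = ("18-35", "36-45", ">46")


@dataclass
class CohortConfig:
    n_participants: int = 43
    # Deployment marginals: 29 men / 14 women; age bins 14 / 18 / 11.
    p_woman: float = 14 / 43
    age_probs: tuple[float, ...] = (14 / 43, 18 / 43, 11 / 43)
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    work_start: time = time(9, 0)
    work_end: time = time(17, 0)
    # Latent temporal-engagement tendency (skewness of engagement hours).
    skewness_mean: float = -0.09
    skewness_sd: float = 0.58
    skewness_cap: float = 1.41

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0 <= self.p_woman <= 1:
            raise ConfigurationError(f"p_woman {self.p_woman} outside [0, 1]")
        if len(self.age_probs) != len(AGE_GROUPS) or abs(sum(self.age_probs) - 1) > 1e-9:
            raise ConfigurationError("age_probs must be 3 probabilities summing to 1")
        for name, spec in self.traits.items():
            spec.validate(name)
        if self.work_start >= self.work_end:
            raise ConfigurationError("work_start must precede work_end")


@dataclass
class ContextConfig:
    """Half-hour telemetry aggregates.

    Count channels use Poisson defaults (meetings, ad hoc calls, self
    events) and negative-binomial defaults (emails, chats, attention) —
    the published per-nudge SDs exceed the means for the latter group, so
    Poisson would be underdispersed.  Means are the per-nudge descriptive
    means of the deployment.
    """

    meetings_mean: float = 0.30
    self_events_mean: float = 0.12
    adhoc_calls_mean: float = 0.04
    emails_sent_mean: float = 0.39
    emails_sent_disp: float = 0.40  # NB size parameter r
    emails_read_mean: float = 3.22
    emails_read_disp: float = 0.46
    chats_mean: float = 3.88
    chats_disp: float = 0.49
    attention_mean: float = 1442.64
    attention_disp: float = 1.2
    attention_cap: int = 5705
    # Emails *received* feed the stress score (distinct from sent/read).
    emails_received_mean: float = 0.75  # per half-hour
    emails_received_disp: float = 0.6
    # Zero-inflated no-meeting minutes, capped at the window length.
    no_meeting_p_nonzero: float = 0.30
    no_meeting_scale: float = 18.0
    window_minutes: int = 30
    # Continuous sensed streams (per engine tick).
    heart_rate_mean: float = 72.0
    heart_rate_between_sd: float = 6.0
    heart_rate_within_sd: float = 3.0
    heart_rate_ar: float = 0.9
    facial_sd: float = 0.9
    facial_ar: float = 0.8
    facial_cap: float = 3.0
    # Day-to-day workload variation (multiplies count rates for a whole
    # day); drives realistic busy-vs-light-day clustering of high stress.
    day_load_sd: float = 0.35
    # EMA stress answers: 1 + Poisson(base + slope * current score), capped
    # at 5.  Low base keeps the cohort in the low-stress regime the study
    # observed.
    ema_rate_base: float = 0.0
    ema_rate_slope: float = 0.8

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ConfigurationError(f"context rate {f.name} must be >= 0, got {v}")


@dataclass
class NormalizerConfig:
    """Clipped min-max floors/caps for the five stress-score components."""

    emails_lo: float = 0.0
    emails_hi: float = 20.0  # emails received per day
    meetings_lo: float = 0.0
    meetings_hi: float = 12.0  # meetings per day
    facial_cap: float = 3.0  # symmetric around 0
    heart_rate_lo: float = 55.0
    heart_rate_hi: float = 110.0


@dataclass
class EngineConfig:
    tick_minutes: int = 5
    daily_nudge_cap: int = 4
    nudge_cooldown_min: int = 120
    completion_cooldown_min: int = 60
    nudge_expiry_min: int = 30
    emas_per_day: int = 5
    ema_min_spacing_min: int = 45
    default_score_baseline: float = 0.5  # midpoint of the [0, 1] score range
    default_ema_baseline: float = 3.0  # midpoint of the 1-5 EMA scale
    trigger_mode: str = "or"  # "or" | "and" | "score" | "ema"
    ema_freshness_min: int = 15  # how long a momentary rating stays current
    allow_repostpone: bool = False
    normalizers: NormalizerConfig = field(default_factory=NormalizerConfig)

    def validate(self) -> None:
        if self.tick_minutes < 1:
            raise ConfigurationError("tick_minutes must be >= 1")
        if self.trigger_mode not in ("or", "and", "score", "ema"):
            raise ConfigurationError(f"unknown trigger_mode {self.trigger_mode!r}")
        for name in ("daily_nudge_cap", "nudge_cooldown_min", "completion_cooldown_min",
                     "nudge_expiry_min", "emas_per_day", "ema_min_spacing_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SimulationConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    context: ContextConfig = field(default_factory=ContextConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    truth: dict[str, Any] = field(default_factory=dict)  # overrides for TruthModels
    weeks: int = 4
    seed: int = 0
    log_scores: bool = False  # emit per-tick stress-score events (bulky)

    def validate(self) -> None:
        self.cohort.validate()
        self.context.validate()
        self.engine.validate()
        if self.weeks < 2:
            raise ConfigurationError(
                "weeks must be >= 2 (week 1 is needed to learn baselines)"
            )


def _update_dataclass(obj: Any, data: dict[str, Any]) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigurationError(f"unknown config field {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value)
        elif key == "traits" and isinstance(value, dict):
            for tname, tval in value.items():
                current[tname] = TraitSpec(**tval)
        elif isinstance(current, time) and isinstance(value, str):
            h, m = value.split(":")
            setattr(obj, key, time(int(h), int(m)))
        else:
            setattr(obj, key, value)


def load_config(path: str | None = None, overrides: dict[str, Any] | None = None
                ) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from defaults, an optional YAML file
    and an optional override mapping (applied in that order)."""
    cfg = SimulationConfig()
    for data in (
        yaml.safe_load(open(path)) if path else None,
        overrides,
    ):
        if data:
            _update_dataclass(cfg, data)
    cfg.validate()
    return cfg
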