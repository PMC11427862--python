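"""Participant profiles and cohort generation.

A profile bundles the per-participant covariates of the analysis (age
group, gender, emotion-regulation skills, resilience, Big Five traits),
the declared working hours, and latent generative-behaviour parameters
used only by the simulator (a temporal-engagement tendency, a resting
heart-rate level, a workload multiplier).

Trait values are drawn from clipped normals with the deployment cohort's
published means/SDs; categorical marginals default to 29 men / 14 women
and age bins 14 / 18 / 11 out of 43.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np

from .config import AGE_GROUPS, CohortConfig, ConfigurationError

TRAIT_NAMES = (
    "cognitive_reappraisal",
    "expressive_suppression",
    "resilience",
    "agreeableness",
    "conscientiousness",
    "extraversion",
    "neuroticism",
    "openness",
)


@dataclass
class ParticipantProfile:
    participant_id: str
    age_group: str
    gender: str  # "man" | "woman"
    traits: dict[str, float]
    work_start: time
    work_end: time
    # Latent generative parameters (not analysis covariates per se).
    latent_skewness: float = 0.0
    hr_mean: float = 72.0
    load_multiplier: float = 1.0
    context_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.gender not in ("man", "woman"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.work_start >= self.work_end:
            raise ValueError("work_start must precede work_end")
        for name, rate in self.context_rates.items():
            if rate < 0:
                raise ValueError(f"context rate {name!r} must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "age_group": self.age_group,
            "gender": self.gender,
            "work_start": self.work_start.strftime("%H:%M"),
            "work_end": self.work_end.strftime("%H:%M"),
            "latent_skewness": self.latent_skewness,
            "hr_mean": self.hr_mean,
            "load_multiplier": self.load_multiplier,
        }
        d.update(self.traits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantProfile":
        def _t(s: str) -> time:
            h, m = s.split(":")
            return time(int(h), int(m))

        return cls(
            participant_id=d["participant_id"],
            age_group=d["age_group"],
            gender=d["gender"],
            traits={k: float(d[k]) for k in TRAIT_NAMES},
            work_start=_t(d["work_start"]),
            work_end=_t(d["work_end"]),
            latent_skewness=float(d.get("latent_skewness", 0.0)),
            hr_mean=float(d.get("hr_mean", 72.0)),
            load_multiplier=float(d.get("load_multiplier", 1.0)),
        )


def participant_rng(seed: int, index: int) -> np.random.Generator:
    """Per-participant substream: adding participants never reshuffles the
    streams of existing ones."""
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def generate_participants(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles reproducibly from ``seed``.

    Trait values are clipped to their instrument ranges; categorical
    marginals match the configured proportions in expectation.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    config = config or CohortConfig()
    config.validate()

    profiles = []
    for i in range(n):
        rng = participant_rng(seed, i)
        traits = {}
        for name, spec in config.traits.items():
            traits[name] = float(
                np.clip(rng.normal(spec.mean, spec.sd), spec.lo, spec.hi)
            )
        age_group = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=config.age_probs)]
        gender = "woman" if rng.random() < config.p_woman else "man"
        skew = float(
            np.clip(
                rng.normal(config.skewness_mean, config.skewness_sd),
                -config.skewness_cap,
                config.skewness_cap,
            )
        )
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i:03d}",
                age_group=age_group,
                gender=gender,
                traits=traits,
                work_start=config.work_start,
                work_end=config.work_end,
                latent_skewness=skew,
                hr_mean=float(rng.normal(72.0, 6.0)),
                load_multiplier=float(np.exp(rng.normal(0.0, 0.35) - 0.35**2 / 2)),
            )
        )
    return profiles
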