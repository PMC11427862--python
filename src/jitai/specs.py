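"""Canonical model specifications for the five outcome analyses.

All five models share the 21-df base design — age group, gender, the two
emotion-regulation scales, resilience, the Big Five, engagement
skewness, per-slot nudge probability (percent), seven telemetry
features (chat counts excluded — contaminated by the delivery channel),
and the trigger source.  The downstream models add the intervention's
category/modality/location and, where applicable, stress and rating
covariates.
"""

from __future__ import annotations

from .models import ModelSpec

BASE_PREDICTORS = (
    "age_group",
    "gender",
    "cognitive_reappraisal",
    "expressive_suppression",
    "resilience",
    "agreeableness",
    "conscientiousness",
    "extraversion",
    "neuroticism",
    "openness",
    "engagement_skewness",
    "nudge_probability",
    "meeting_counts",
    "no_meeting_minutes",
    "self_event_counts",
    "email_messages_sent",
    "email_messages_read",
    "ad_hoc_call_count",
    "attention_signals",
    "trigger_source",
)

INTERVENTION_PREDICTORS = ("category", "modality", "location")

ENGAGED_SPEC = ModelSpec(
    name="engaged",
    outcome="engaged",
    predictors=BASE_PREDICTORS,
    scope="per_nudge",
)

DISTRACT_CHOSEN_SPEC = ModelSpec(
    name="distract_chosen", outcome="distract_chosen",
    predictors=BASE_PREDICTORS, scope="chosen",
)
CALM_CHOSEN_SPEC = ModelSpec(
    name="calm_chosen", outcome="calm_chosen",
    predictors=BASE_PREDICTORS, scope="chosen",
)
ADDRESS_CHOSEN_SPEC = ModelSpec(
    name="address_chosen", outcome="address_chosen",
    predictors=BASE_PREDICTORS, scope="chosen",
)

ENGAGED_AFTER_CHOSEN_SPEC = ModelSpec(
    name="engaged_after_chosen",
    outcome="engaged",
    predictors=BASE_PREDICTORS + INTERVENTION_PREDICTORS,
    scope="chosen",
)

LIKED_SPEC = ModelSpec(
    name="liked",
    outcome="liked",
    predictors=BASE_PREDICTORS + ("category", "stress_reduction", "modality", "location"),
    scope="completed",
)

IMPROVED_SPEC = ModelSpec(
    name="improved",
    outcome="improved",
    predictors=BASE_PREDICTORS + ("category", "stress_before", "rating", "modality", "location"),
    scope="completed",
)

#: The report's five outcome analyses (the category choice counts as one,
#: fitted as three binary models).
ALL_SPECS = (
    ENGAGED_SPEC,
    DISTRACT_CHOSEN_SPEC,
    CALM_CHOSEN_SPEC,
    ADDRESS_CHOSEN_SPEC,
    ENGAGED_AFTER_CHOSEN_SPEC,
    LIKED_SPEC,
    IMPROVED_SPEC,
)
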