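"""The microintervention catalog.

Interventions are under-5-minute stress-reduction activities translated
from CBT/DBT components.  Each item has a functional category
(``distract`` = get my mind off work, ``calm`` = feel calm and present,
``address`` = think through my stress), a delivery modality and an
intended location.  The bundled default catalog carries 18 items per
category, with within-category modality/location composition matching the
deployment's chosen-intervention marginals (mostly prompts performed at
the desk, a few videos, a single chatbot conversation per category).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

CATEGORIES = ("distract", "calm", "address")
MODALITIES = ("video", "prompt", "conversation")
LOCATIONS = ("at_desk", "inside", "outside")

ITEMS_PER_CATEGORY = 18


@dataclass(frozen=True)
class Intervention:
    intervention_id: str
    category: str
    modality: str
    location: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")


# 18 (modality, location) assignments reused for every category:
# 13 prompts / 4 videos / 1 conversation; 14 at-desk / 3 inside / 1 outside.
_COMPOSITION = (
    [("prompt", "at_desk")] * 10
    + [("prompt", "inside")] * 2
    + [("prompt", "outside")]
    + [("video", "at_desk")] * 3
    + [("video", "inside")]
    + [("conversation", "at_desk")]
)
assert len(_COMPOSITION) == ITEMS_PER_CATEGORY


def default_catalog() -> list[Intervention]:
    """Return the bundled 54-item catalog (18 per functional category)."""
    items = []
    for category in CATEGORIES:
        for i, (modality, location) in enumerate(_COMPOSITION, start=1):
            items.append(
                Intervention(f"{category}_{i:02d}", category, modality, location)
            )
    return items


def write_catalog_csv(items: list[Intervention], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intervention_id", "category", "modality", "location"])
        for it in items:
            writer.writerow([it.intervention_id, it.category, it.modality, it.location])


def read_catalog_csv(path: str | Path) -> list[Intervention]:
    with open(path, newline="") as fh:
        return [
            Intervention(
                row["intervention_id"], row["category"], row["modality"], row["location"]
            )
            for row in csv.DictReader(fh)
        ]
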