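"""Behavioral-factor action space and the daily text-message template library.

Each daily message is composed from five behavioral factors: framing
(neutral / positive / negative), observed feedback on the prior week's
pill-bottle record ("history"), social reinforcement, reminder-vs-informational
content, and a reflective question.  The framing level contributes two
indicator columns (positive, negative) with neutral as the reference, so the
factor space maps onto six binary indicators used throughout the package.

Concrete wording is out of scope: templates carry placeholder texts with
named slots (``{first_name}``, and ``{adherent_days_last_week}`` when the
history flag is on) so rendering stays a harness concern.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np


class Framing(str, Enum):
    neutral = "neutral"
    positive = "positive"
    negative = "negative"


class Content(str, Enum):
    reminder = "reminder"
    informational = "informational"


#: Canonical order of the six binary factor indicators.
FACTOR_NAMES: tuple[str, ...] = (
    "framing_positive",
    "framing_negative",
    "history",
    "social",
    "content_informational",
    "reflective",
)
N_FACTORS = len(FACTOR_NAMES)


@dataclass(frozen=True)
class FactorVector:
    """One day's message composition over the five behavioral factors."""

    framing: Framing = Framing.neutral
    history: bool = False
    social: bool = False
    content: Content = Content.reminder
    reflective: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "framing", Framing(self.framing))
        object.__setattr__(self, "content", Content(self.content))

    def indicators(self) -> np.ndarray:
        """Six 0/1 indicators in :data:`FACTOR_NAMES` order."""
        return np.array(
            [
                self.framing is Framing.positive,
                self.framing is Framing.negative,
                self.history,
                self.social,
                self.content is Content.informational,
                self.reflective,
            ],
            dtype=float,
        )

    @classmethod
    def from_indicators(cls, ind: Iterable[float]) -> "FactorVector":
        pos, neg, hist, soc, info, refl = (bool(round(float(v))) for v in ind)
        if pos and neg:
            raise ValueError("framing cannot be both positive and negative")
        framing = Framing.positive if pos else Framing.negative if neg else Framing.neutral
        return cls(
            framing=framing,
            history=hist,
            social=soc,
            content=Content.informational if info else Content.reminder,
            reflective=refl,
        )


def all_factor_vectors() -> list[FactorVector]:
    """Enumerate the 48 admissible combinations (3 x 2 x 2 x 2 x 2)."""
    combos = itertools.product(
        list(Framing), [False, True], [False, True], list(Content), [False, True]
    )
    return [
        FactorVector(framing=f, history=h, social=s, content=c, reflective=r)
        for f, h, s, c, r in combos
    ]


@dataclass(frozen=True)
class MessageTemplate:
    template_id: str
    factor_set: FactorVector
    text: str


class MissingCoverageError(KeyError):
    """Raised when no template matches a requested factor set."""


@dataclass
class Catalog:
    """A template library indexed by factor set.

    Invariants: every catalog factor set has >= 2 templates and each template
    belongs to exactly one factor set.
    """

    templates: list[MessageTemplate] = field(default_factory=list)

    def factor_sets(self) -> list[FactorVector]:
        seen: dict[FactorVector, None] = {}
        for t in self.templates:
            seen.setdefault(t.factor_set)
        return list(seen)

    def matching(self, factors: FactorVector) -> list[MessageTemplate]:
        return [t for t in self.templates if t.factor_set == factors]

    def to_json(self) -> str:
        rows = [
            {
                "template_id": t.template_id,
                "framing": t.factor_set.framing.value,
                "history": t.factor_set.history,
                "social": t.factor_set.social,
                "content": t.factor_set.content.value,
                "reflective": t.factor_set.reflective,
                "text": t.text,
            }
            for t in self.templates
        ]
        return json.dumps(rows, indent=1)

    @classmethod
    def from_json(cls, payload: str) -> "Catalog":
        rows = json.loads(payload)
        templates = [
            MessageTemplate(
                template_id=r["template_id"],
                factor_set=FactorVector(
                    framing=r["framing"],
                    history=bool(r["history"]),
                    social=bool(r["social"]),
                    content=r["content"],
                    reflective=bool(r["reflective"]),
                ),
                text=r["text"],
            )
            for r in rows
        ]
        return cls(templates=templates)


_OPENERS = (
    "Hi {first_name}.",
    "Hello {first_name}.",
    "Good morning {first_name}.",
    "{first_name},",
)
_REMINDER_BODY = (
    "it's time to take your diabetes medication today.",
    "remember your diabetes medication today.",
)
_INFO_BODY = (
    "taking your diabetes medication daily keeps your blood sugar steady.",
    "daily diabetes medication works best when taken at the same time.",
)
_FRAMING_CLAUSE = {
    Framing.neutral: "",
    Framing.positive: " Staying on track helps you feel your best.",
    Framing.negative: " Missed doses can let blood sugar rise out of range.",
}
_HISTORY_CLAUSE = " You took your medication on {adherent_days_last_week} of the last 7 days."
_SOCIAL_CLAUSE = " Your loved ones are glad you look after your health."
_REFLECTIVE_CLAUSE = " What would make taking it easier tomorrow?"


def _placeholder_text(fs: FactorVector, variant: int, rng: np.random.Generator) -> str:
    opener = _OPENERS[int(rng.integers(len(_OPENERS)))]
    body_bank = _INFO_BODY if fs.content is Content.informational else _REMINDER_BODY
    body = body_bank[variant % len(body_bank)]
    text = f"{opener} {body}{_FRAMING_CLAUSE[fs.framing]}"
    if fs.history:
        text += _HISTORY_CLAUSE
    if fs.social:
        text += _SOCIAL_CLAUSE
    if fs.reflective:
        text += _REFLECTIVE_CLAUSE
    return text


def build_catalog(n_templates_per_set: int = 2, seed: int = 0) -> Catalog:
    """Build a synthetic catalog covering every admissible factor combination.

    Parameters
    ----------
    n_templates_per_set
        Templates authored per factor set; at least 2 so random template
        selection within a set is always non-degenerate.
    seed
        Seeds the (cosmetic) phrasing variation; catalogs are deterministic
        for a given seed.
    """
    if n_templates_per_set < 2:
        raise ValueError(
            "n_templates_per_set must be >= 2 (each factor set needs at least "
            f"two templates); got {n_templates_per_set}"
        )
    rng = np.random.default_rng(seed)
    templates: list[MessageTemplate] = []
    for i, fs in enumerate(all_factor_vectors()):
        for j in range(n_templates_per_set):
            templates.append(
                MessageTemplate(
                    template_id=f"T{i:02d}-{j}",
                    factor_set=fs,
                    text=_placeholder_text(fs, j, rng),
                )
            )
    return Catalog(templates=templates)


def select_template(
    catalog: Catalog, factors: FactorVector, rng: np.random.Generator
) -> MessageTemplate:
    """Uniformly select one template among those matching ``factors``."""
    matches = catalog.matching(factors)
    if not matches:
        raise MissingCoverageError(f"catalog has no template for factor set {factors}")
    return matches[int(rng.integers(len(matches)))]
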