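"""Attribute/level universe for choice-based conjoint (CBC) surveys.

A CBC concept is one hypothetical program profile: one level chosen per
attribute.  The default instance is the five-attribute PrEP-delivery space
(dosing method, monthly cost, clinician interaction, dispensing venue,
burden of visits to start) with 13 levels in total, plus the single
feasibility prohibition that injectable dosing cannot be combined with
mail delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


class ConfigurationError(ValueError):
    """Raised when an attribute space, prohibition set, or design request is malformed."""


@dataclass(frozen=True)
class Attribute:
    """A named attribute with an ordered set of level labels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"unknown level {label!r} for attribute {self.name!r}"
            ) from None


@dataclass(frozen=True)
class Prohibition:
    """A pair of (attribute, level) values that may not co-occur in one concept."""

    attr_a: str
    level_a: str
    attr_b: str
    level_b: str

    def as_indices(self, space: "AttributeSpace") -> tuple[int, int, int, int]:
        ia = space.attr_index(self.attr_a)
        ib = space.attr_index(self.attr_b)
        la = space.attributes[ia].level_index(self.level_a)
        lb = space.attributes[ib].level_index(self.level_b)
        return ia, la, ib, lb


@dataclass(frozen=True)
class AttributeSpace:
    """An ordered collection of attributes defining the concept universe."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigurationError("attribute names must be unique")

    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def level_counts(self) -> list[int]:
        return [a.n_levels for a in self.attributes]

    @property
    def total_levels(self) -> int:
        return sum(self.level_counts)

    def attr_index(self, name: str) -> int:
        for i, a in enumerate(self.attributes):
            if a.name == name:
                return i
        raise ConfigurationError(f"unknown attribute {name!r}")

    def level_labels(self) -> list[tuple[str, str]]:
        """All (attribute, level) label pairs in order."""
        return [(a.name, lev) for a in self.attributes for lev in a.levels]

    def validate_prohibitions(self, prohibitions: Iterable[Prohibition]) -> None:
        for p in prohibitions:
            p.as_indices(self)
            if p.attr_a == p.attr_b:
                raise ConfigurationError(
                    f"prohibition references the same attribute twice: {p.attr_a!r}"
                )


@dataclass(frozen=True)
class Concept:
    """One program profile: a level index per attribute, in attribute order."""

    levels: tuple[int, ...]

    def violates(self, space: AttributeSpace, prohibitions: Sequence[Prohibition]) -> bool:
        for p in prohibitions:
            ia, la, ib, lb = p.as_indices(space)
            if self.levels[ia] == la and self.levels[ib] == lb:
                return True
        return False

    def labels(self, space: AttributeSpace) -> dict[str, str]:
        return {
            a.name: a.levels[lev] for a, lev in zip(space.attributes, self.levels)
        }


# --- default PrEP-delivery instance -------------------------------------------------

DOSING = "dosing"
COST = "cost"
CLINICIAN = "clinician_interaction"
DISPENSING = "dispensing_venue"
BURDEN = "visit_burden"

INJECTABLE = "Injectable PrEP"
ON_DEMAND = "On-demand PrEP"
DAILY_ORAL = "Daily oral PrEP"
COST_HIGH = "RM 250-350"
COST_LOW = "RM 125-249"
IN_PERSON = "In-person"
ONLINE = "Online"
TEXT_BASED = "Text-based"
COURIER = "Private courier"
MAIL = "Mail delivery"
PICKUP = "Self pick-up"
SAME_DAY = "Same day"
ONE_WEEK = "One week wait"


def default_attributes() -> AttributeSpace:
    """The five-attribute PrEP delivery space (13 levels in total)."""
    return AttributeSpace(
        (
            Attribute(DOSING, (INJECTABLE, ON_DEMAND, DAILY_ORAL)),
            Attribute(COST, (COST_HIGH, COST_LOW)),
            Attribute(CLINICIAN, (IN_PERSON, ONLINE, TEXT_BASED)),
            Attribute(DISPENSING, (COURIER, MAIL, PICKUP)),
            Attribute(BURDEN, (SAME_DAY, ONE_WEEK)),
        )
    )


def default_prohibitions() -> tuple[Prohibition, ...]:
    """Infeasible combinations: injectable dosing cannot be mailed."""
    return (Prohibition(DOSING, INJECTABLE, DISPENSING, MAIL),)
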