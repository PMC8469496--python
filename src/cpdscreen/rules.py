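"""Discriminant rules: score definitions with cutoffs and orientations.

A :class:`DiscriminantRule` scores a sample either from a single CPD
parameter or from a product/quotient composite (positively oriented
parameters in the numerator, negatively oriented in the denominator), then
compares the score against a cutoff.  Comparisons are strict: a score
exactly equal to the cutoff is always classified with the negative label,
matching the strict inequalities the cutoffs were published with and giving
deterministic tie handling.

The published registry ships the screening discriminants for neoplastic vs
non-neoplastic blood samples (four single neutrophil/lymphocyte/monocyte
parameters and the composite
``(SD-V-NE x MN-UMALS-LY x SD-AL2-MO) / MN-C-NE`` at cutoff 106.44), the
reactive-vs-neoplastic discriminant (MN-AL2-NE at 147.5), and the
leukaemia-subtype flags (AML, APL, ALL, CLL).  Cutoff orientations that
were not published alongside the cutoffs are shipped as provisional
defaults and are configurable; the calibration module can re-learn them
from data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .cohort import NEOPLASTIC, NON_NEOPLASTIC, CPDRecord
from .parameters import CPDParameter, parse_parameter

HIGH_IS_POSITIVE = "high_is_positive"
LOW_IS_POSITIVE = "low_is_positive"
ORIENTATIONS = (HIGH_IS_POSITIVE, LOW_IS_POSITIVE)


class MissingParameterError(ValueError):
    """A rule references a parameter absent from the record."""


class ScoreDomainError(ValueError):
    """The score is mathematically undefined (zero denominator)."""


class OrientationError(ValueError):
    """A rule is applied without a configured cutoff orientation."""


@dataclass(frozen=True)
class DiscriminantRule:
    """A scored decision rule with an explicit cutoff orientation.

    ``numerator`` parameters multiply into the score; ``denominator``
    parameters divide it.  A single-parameter rule has one numerator
    entry and an empty denominator.  ``orientation`` may be None only
    for rules whose published direction is unknown; applying such a rule
    raises :class:`OrientationError` rather than guessing.
    """

    name: str
    numerator: tuple[CPDParameter, ...]
    cutoff: float
    orientation: str | None
    positive_label: str
    negative_label: str
    denominator: tuple[CPDParameter, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError(f"rule {self.name!r}: cutoff must be finite")
        if self.orientation is not None and self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"rule {self.name!r}: orientation must be one of {ORIENTATIONS}"
            )
        if not self.numerator:
            raise ValueError(f"rule {self.name!r}: needs at least one parameter")

    @property
    def parameters(self) -> tuple[CPDParameter, ...]:
        return self.numerator + self.denominator

    def score(self, record: CPDRecord) -> float:
        """Evaluate the rule's score on a record.

        Raises :class:`MissingParameterError` naming the first absent
        parameter, and :class:`ScoreDomainError` if any denominator value
        is zero (never returns infinity).
        """
        for p in self.parameters:
            if p not in record.values:
                raise MissingParameterError(
                    f"rule {self.name!r}: record {record.sample_id!r} is "
                    f"missing parameter {p}"
                )
        num = math.prod(record.values[p] for p in self.numerator)
        den = math.prod(record.values[p] for p in self.denominator)
        if self.denominator and den == 0.0:
            raise ScoreDomainError(
                f"rule {self.name!r}: zero denominator on record "
                f"{record.sample_id!r}; score undefined"
            )
        return num / den if self.denominator else num

    def decide(self, score: float) -> str:
        """Positive/negative label for a score; equality is negative."""
        if self.orientation is None:
            raise OrientationError(
                f"rule {self.name!r}: cutoff orientation is not configured; "
                "refusing to guess which side is positive"
            )
        if self.orientation == HIGH_IS_POSITIVE:
            positive = score > self.cutoff
        else:
            positive = score < self.cutoff
        return self.positive_label if positive else self.negative_label

    def with_orientation(self, orientation: str) -> "DiscriminantRule":
        return replace(self, orientation=orientation)


def single_rule(
    parameter: str | CPDParameter,
    cutoff: float,
    orientation: str | None,
    positive_label: str,
    negative_label: str,
    name: str | None = None,
) -> DiscriminantRule:
    """Convenience constructor for a single-parameter rule."""
    param = parse_parameter(parameter) if isinstance(parameter, str) else parameter
    return DiscriminantRule(
        name=name or str(param),
        numerator=(param,),
        cutoff=cutoff,
        orientation=orientation,
        positive_label=positive_label,
        negative_label=negative_label,
    )


REACTIVE = "reactive"

# -- Published screening discriminants (neoplastic vs non-neoplastic). ------
# Orientations here were published with the cutoffs (the neoplastic side of
# each cutoff is printed): SD-V-NE high, MN-C-NE low, MN-UMALS-LY high,
# SD-AL2-MO high, composite high.

COMPOSITE_NEOPLASTIC_RULE = DiscriminantRule(
    name="composite-neoplastic",
    numerator=(
        parse_parameter("SD-V-NE"),
        parse_parameter("MN-UMALS-LY"),
        parse_parameter("SD-AL2-MO"),
    ),
    denominator=(parse_parameter("MN-C-NE"),),
    cutoff=106.44,
    orientation=HIGH_IS_POSITIVE,
    positive_label=NEOPLASTIC,
    negative_label=NON_NEOPLASTIC,
)

SINGLE_SCREENING_RULES = (
    single_rule("SD-V-NE", 18.95, HIGH_IS_POSITIVE, NEOPLASTIC, NON_NEOPLASTIC),
    single_rule("MN-C-NE", 148.50, LOW_IS_POSITIVE, NEOPLASTIC, NON_NEOPLASTIC),
    single_rule("MN-UMALS-LY", 59.50, HIGH_IS_POSITIVE, NEOPLASTIC, NON_NEOPLASTIC),
    single_rule("SD-AL2-MO", 16.20, HIGH_IS_POSITIVE, NEOPLASTIC, NON_NEOPLASTIC),
)

# Direction of the reactive discriminant was not published with its cutoff;
# low_is_positive(neoplastic) is the shipped provisional default (reactive
# neutrophils absorb more axial light than blast-diluted populations).
REACTIVE_RULE = single_rule(
    "MN-AL2-NE", 147.5, LOW_IS_POSITIVE, NEOPLASTIC, REACTIVE,
    name="reactive-discriminant",
)

# Subtype flag cutoffs were published without directions; all shipped
# defaults are high_is_positive and provisional (configurable).
SUBTYPE_RULES: dict[str, tuple[DiscriminantRule, ...]] = {
    "AML": (
        single_rule("SD-MALS-NE", 15.81, HIGH_IS_POSITIVE, "AML", "other"),
        single_rule("SD-UMALS-NE", 17.70, HIGH_IS_POSITIVE, "AML", "other"),
    ),
    "APL": (
        single_rule("MN-V-NE", 159.50, HIGH_IS_POSITIVE, "APL", "other"),
        single_rule("SD-V-MO", 33.68, HIGH_IS_POSITIVE, "APL", "other"),
    ),
    "ALL": (
        single_rule("MN-MALS-NE", 129.50, HIGH_IS_POSITIVE, "ALL", "other"),
        single_rule("MN-LMALS-NE", 122.50, HIGH_IS_POSITIVE, "ALL", "other"),
    ),
    "CLL": (
        single_rule("SD-C-MO", 11.10, HIGH_IS_POSITIVE, "CLL", "other"),
    ),
}


@dataclass
class RulesRegistry:
    """Complete rule set the screening cascade consumes."""

    composite: DiscriminantRule = field(
        default_factory=lambda: COMPOSITE_NEOPLASTIC_RULE
    )
    reactive: DiscriminantRule = field(default_factory=lambda: REACTIVE_RULE)
    subtypes: dict[str, tuple[DiscriminantRule, ...]] = field(
        default_factory=lambda: dict(SUBTYPE_RULES)
    )
    singles: tuple[DiscriminantRule, ...] = field(
        default_factory=lambda: SINGLE_SCREENING_RULES
    )


def _rule_to_dict(rule: DiscriminantRule) -> dict:
    d = {
        "name": rule.name,
        "numerator": [str(p) for p in rule.numerator],
        "cutoff": float(rule.cutoff),
        "orientation": rule.orientation,
        "positive_label": rule.positive_label,
        "negative_label": rule.negative_label,
    }
    if rule.denominator:
        d["denominator"] = [str(p) for p in rule.denominator]
    return d


def _rule_from_dict(d: dict) -> DiscriminantRule:
    return DiscriminantRule(
        name=d["name"],
        numerator=tuple(parse_parameter(p) for p in d["numerator"]),
        denominator=tuple(parse_parameter(p) for p in d.get("denominator", [])),
        cutoff=float(d["cutoff"]),
        orientation=d.get("orientation"),
        positive_label=d["positive_label"],
        negative_label=d["negative_label"],
    )


def save_rules(registry: RulesRegistry, path: str | Path) -> None:
    """Write a registry as YAML (the same schema ``load_rules`` reads)."""
    doc = {
        "schema": "cpdscreen-rules/1",
        "composite": _rule_to_dict(registry.composite),
        "reactive": _rule_to_dict(registry.reactive),
        "subtypes": {
            name: [_rule_to_dict(r) for r in rules]
            for name, rules in registry.subtypes.items()
        },
        "singles": [_rule_to_dict(r) for r in registry.singles],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_rules(path: str | Path | None = None) -> RulesRegistry:
    """Load a rules registry from YAML; None loads the published defaults."""
    if path is None:
        text = (
            resources.files("cpdscreen").joinpath("data/published_rules.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return RulesRegistry(
        composite=_rule_from_dict(doc["composite"]),
        reactive=_rule_from_dict(doc["reactive"]),
        subtypes={
            name: tuple(_rule_from_dict(r) for r in rules)
            for name, rules in doc.get("subtypes", {}).items()
        },
        singles=tuple(_rule_from_dict(r) for r in doc.get("singles", [])),
    )
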