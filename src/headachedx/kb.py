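"""Knowledge base of diagnostic criteria for primary headache disorders.

The package models a diagnosis rulebook (ICHD-style criteria) as a small
declarative knowledge base: a vocabulary of discrete patient attributes and,
per diagnosis, a *class concept* -- a conjunction of restrictions over that
vocabulary.  Concepts play three roles downstream:

* they are sampled from to generate constraint-consistent synthetic patients
  (:mod:`headachedx.synth`, :mod:`headachedx.balance`),
* they are rendered as knowledge graphs and compared against encoded patient
  samples with graph kernels (:mod:`headachedx.kernels`),
* they let us count how far a patient deviates from the criteria of a
  diagnosis, which can raise an alert for atypical presentations.

The schema is a plain YAML/JSON document rather than OWL: the restrictions
exercised here (one-of / fixed / subset-of / at-least-m-of) do not need a
description-logic reasoner, and a declarative file keeps the criteria
reviewable by clinicians.  A Turtle export of the derived concept graphs is
available through :mod:`headachedx.codec`.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

# Attribute kinds
ORDINAL = "ordinal-categorical"
NOMINAL = "nominal-categorical"
BINARY = "binary"
SET_VALUED = "set-valued"
KINDS = (ORDINAL, NOMINAL, BINARY, SET_VALUED)

# Restriction kinds
ONE_OF = "one-of"
FIXED = "fixed"
SUBSET_OF = "subset-of"
AT_LEAST_M_OF = "at-least-m-of"
RESTRICTION_KINDS = (ONE_OF, FIXED, SUBSET_OF, AT_LEAST_M_OF)
_SCALAR_RESTRICTIONS = (ONE_OF, FIXED)
_SET_RESTRICTIONS = (SUBSET_OF, AT_LEAST_M_OF)

#: Predicate prefix used when rendering attributes as graph edges.
PREDICATE_PREFIX = "has-"
#: Predicate carrying class-label information on annotated samples.
TYPE_PREDICATE = "is-type"
#: Root node identifier of concept graphs.
CONCEPT_ROOT = "concept"

#: Default alert threshold: a patient deviating from the criteria of their
#: putative diagnosis in at least this many restrictions is flagged for
#: special attention by the physician.
DEFAULT_ALERT_THRESHOLD = 2


class SchemaError(ValueError):
    """A knowledge-base schema document failed validation."""


@dataclass(frozen=True)
class AttributeSpec:
    """One discrete patient attribute and its (ordered) value domain."""

    name: str
    kind: str
    domain: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", tuple(str(v) for v in self.domain))
        if self.kind not in KINDS:
            raise SchemaError(
                f"attribute {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {KINDS})"
            )
        if not self.domain:
            raise SchemaError(f"attribute {self.name!r}: empty domain")
        if len(set(self.domain)) != len(self.domain):
            raise SchemaError(f"attribute {self.name!r}: duplicate domain tokens")
        if self.kind == BINARY and self.domain != ("false", "true"):
            raise SchemaError(
                f"attribute {self.name!r}: binary domain must be "
                f"('false', 'true'), got {self.domain}"
            )

    @property
    def is_set_valued(self) -> bool:
        return self.kind == SET_VALUED


@dataclass(frozen=True)
class Restriction:
    """One conjunct of a class concept: a constraint on a single attribute.

    ``one-of`` / ``fixed`` constrain a scalar attribute to a value set (a
    singleton for ``fixed``); ``subset-of`` caps the members of a set-valued
    attribute; ``at-least-m-of`` demands at least ``m`` of ``values`` to be
    present in a set-valued attribute.
    """

    attribute: str
    kind: str
    values: tuple[str, ...]
    m: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(str(v) for v in self.values))
        if self.kind not in RESTRICTION_KINDS:
            raise SchemaError(
                f"restriction on {self.attribute!r}: unknown kind {self.kind!r}"
            )
        if not self.values:
            raise SchemaError(f"restriction on {self.attribute!r}: empty values")
        if len(set(self.values)) != len(self.values):
            raise SchemaError(f"restriction on {self.attribute!r}: duplicate values")
        if self.kind == FIXED and len(self.values) != 1:
            raise SchemaError(
                f"fixed restriction on {self.attribute!r} must have exactly "
                f"one value, got {len(self.values)}"
            )
        if self.kind == AT_LEAST_M_OF:
            if self.m is None or self.m < 1 or self.m > len(self.values):
                raise SchemaError(
                    f"at-least-m-of restriction on {self.attribute!r}: "
                    f"m={self.m} not in 1..{len(self.values)}"
                )
        elif self.m is not None:
            raise SchemaError(
                f"restriction on {self.attribute!r}: m only applies to "
                f"{AT_LEAST_M_OF}"
            )

    def is_satisfied_by(self, value) -> bool:
        """Whether ``value`` (token, or set of tokens) meets this restriction."""
        if self.kind in _SCALAR_RESTRICTIONS:
            return value in self.values
        members = set(value) if value is not None else set()
        if self.kind == SUBSET_OF:
            return members <= set(self.values)
        # at-least-m-of
        return len(members & set(self.values)) >= (self.m or 1)


@dataclass(frozen=True)
class ClassConcept:
    """The knowledge-base representation of one diagnosis.

    Restrictions are conjunctive: a sample complies with the concept iff it
    satisfies every restriction.
    """

    label: str
    restrictions: tuple[Restriction, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "restrictions", tuple(self.restrictions))


@dataclass(frozen=True)
class KnowledgeGraph:
    """A set of (subject, predicate, object) triples with a root subject."""

    triples: frozenset[tuple[str, str, str]]
    root: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "triples", frozenset(self.triples))
        if self.triples and self.root not in {s for s, _, _ in self.triples}:
            raise ValueError(
                f"root {self.root!r} is not the subject of any triple"
            )

    def __len__(self) -> int:
        return len(self.triples)


@dataclass(frozen=True)
class KnowledgeBase:
    """Attribute vocabulary plus one class concept per diagnosis."""

    attributes: tuple[AttributeSpec, ...]
    concepts: tuple[ClassConcept, ...]
    _by_name: dict = field(default=None, repr=False, compare=False)
    _by_label: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "concepts", tuple(self.concepts))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names")
        labels = [c.label for c in self.concepts]
        if len(set(labels)) != len(labels):
            raise SchemaError(f"duplicate class labels in {labels}")
        if len(self.concepts) < 2:
            raise SchemaError("a knowledge base needs at least two concepts")
        object.__setattr__(self, "_by_name", {a.name: a for a in self.attributes})
        object.__setattr__(self, "_by_label", {c.label: c for c in self.concepts})
        for concept in self.concepts:
            for r in concept.restrictions:
                self._validate_restriction(concept.label, r)

    def _validate_restriction(self, label: str, r: Restriction) -> None:
        spec = self._by_name.get(r.attribute)
        if spec is None:
            raise SchemaError(
                f"concept {label!r}: restriction references unknown "
                f"attribute {r.attribute!r}"
            )
        bad = set(r.values) - set(spec.domain)
        if bad:
            raise SchemaError(
                f"concept {label!r}: restriction on {r.attribute!r} uses "
                f"values outside the domain: {sorted(bad)}"
            )
        if spec.is_set_valued and r.kind in _SCALAR_RESTRICTIONS:
            raise SchemaError(
                f"concept {label!r}: {r.kind} restriction is not applicable "
                f"to set-valued attribute {r.attribute!r}"
            )
        if not spec.is_set_valued and r.kind in _SET_RESTRICTIONS:
            raise SchemaError(
                f"concept {label!r}: {r.kind} restriction requires a "
                f"set-valued attribute, {r.attribute!r} is {spec.kind}"
            )

    # -- lookup -----------------------------------------------------------

    @property
    def C(self) -> int:
        """Number of diagnosis classes."""
        return len(self.concepts)

    @property
    def class_labels(self) -> list[str]:
        return [c.label for c in self.concepts]

    def attribute(self, name: str) -> AttributeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown attribute {name!r}") from None

    def concept(self, label: str) -> ClassConcept:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown class label {label!r}") from None

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a.name, "kind": a.kind, "domain": list(a.domain)}
                for a in self.attributes
            ],
            "concepts": [
                {
                    "label": c.label,
                    "restrictions": [
                        {
                            "attribute": r.attribute,
                            "kind": r.kind,
                            "values": list(r.values),
                            **({"m": r.m} if r.m is not None else {}),
                        }
                        for r in c.restrictions
                    ],
                }
                for c in self.concepts
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KnowledgeBase":
        if not isinstance(doc, Mapping):
            raise SchemaError("schema document must be a mapping")
        try:
            attrs = [
                AttributeSpec(a["name"], a["kind"], tuple(a["domain"]))
                for a in doc.get("attributes", [])
            ]
            concepts = [
                ClassConcept(
                    str(c["label"]),
                    tuple(
                        Restriction(
                            r["attribute"],
                            r["kind"],
                            tuple(r["values"]),
                            r.get("m"),
                        )
                        for r in c.get("restrictions", [])
                    ),
                )
                for c in doc.get("concepts", [])
            ]
        except KeyError as exc:
            raise SchemaError(f"schema entry missing required key {exc}") from None
        return cls(tuple(attrs), tuple(concepts))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_knowledge_base(source) -> KnowledgeBase:
    """Load and validate a knowledge-base schema.

    ``source`` may be a path to a YAML/JSON file, or a YAML/JSON string.
    Loading, saving and re-loading a schema yields an identical
    :class:`KnowledgeBase`.
    """
    text = None
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" not in s and (s.endswith((".yaml", ".yml", ".json"))):
            with open(s) as fh:
                text = fh.read()
        else:
            text = s
    doc = yaml.safe_load(text)
    return KnowledgeBase.from_dict(doc)


# -- concept graphs --------------------------------------------------------


def predicate_for(attribute: str) -> str:
    return PREDICATE_PREFIX + attribute


def concept_graph(kb: KnowledgeBase, label: str) -> KnowledgeGraph:
    """Render a class concept as a knowledge graph.

    For every restriction, one ``(root, has-<attribute>, value)`` triple per
    allowed value -- the union of the restriction's value set.  The graph
    deliberately carries *no* class-label (typing) triple, so it can be
    compared against unlabeled patient graphs by a graph kernel.
    """
    concept = kb.concept(label)
    triples = {
        (CONCEPT_ROOT, predicate_for(r.attribute), v)
        for r in concept.restrictions
        for v in r.values
    }
    return KnowledgeGraph(frozenset(triples), CONCEPT_ROOT)


# -- deviation counting ----------------------------------------------------


def _sample_values(sample) -> Mapping:
    if isinstance(sample, Mapping):
        return sample
    return sample.values


def count_deviations(
    sample, concept: ClassConcept, tau: int = DEFAULT_ALERT_THRESHOLD
) -> tuple[int, bool]:
    """Count how many restrictions of ``concept`` the sample violates.

    Returns ``(deviations, alert)`` where ``alert`` is raised when the count
    reaches the threshold ``tau``.  A sample missing an attribute referenced
    by a restriction conservatively counts as one violation (and is logged).
    """
    values = _sample_values(sample)
    deviations = 0
    for r in concept.restrictions:
        if r.attribute not in values:
            logger.warning(
                "sample missing attribute %r required by concept %r; "
                "counted as a deviation",
                r.attribute,
                concept.label,
            )
            deviations += 1
        elif not r.is_satisfied_by(values[r.attribute]):
            deviations += 1
    return deviations, deviations >= tau


def satisfies(sample, concept: ClassConcept) -> bool:
    """True iff the sample meets every restriction of the concept."""
    return count_deviations(sample, concept)[0] == 0


# -- bundled fixture -------------------------------------------------------


def fixture_knowledge_base() -> KnowledgeBase:
    """The bundled migbase-style knowledge base.

    Vocabulary mirrors the migbase questionnaire schema (duration buckets
    A-J, location, severity, characterisation, previous-attack buckets and a
    set-valued symptom list); the three concepts are simplified ICHD-3
    criteria for migraine, tension-type and cluster headache, shipped as a
    test/demo fixture.
    """
    from importlib import resources

    ref = resources.files("headachedx").joinpath("data/fixture_kb.yaml")
    return load_knowledge_base(ref.read_text())


#: Second-ranges of the migbase duration buckets (closed intervals; the last
#: bucket is open-ended and capped at four weeks for generation purposes).
DURATION_BUCKET_SECONDS: dict[str, tuple[int, int]] = {
    "A": (0, 4),
    "B": (5, 119),
    "C": (120, 239),
    "D": (240, 899),
    "E": (900, 1799),
    "F": (1800, 10799),
    "G": (10800, 14399),
    "H": (14400, 259199),
    "I": (259200, 604799),
    "J": (604800, 2419200),
}


def duration_bucket(seconds: float) -> str:
    """Map an attack duration in seconds to its migbase bucket A-J."""
    if seconds < 0:
        raise ValueError(f"negative duration: {seconds}")
    for bucket, (lo, hi) in DURATION_BUCKET_SECONDS.items():
        if lo <= seconds <= hi:
            return bucket
    return "J"
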