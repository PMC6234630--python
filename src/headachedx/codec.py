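"""Feature extraction, semantic encoding and decoding.

This module owns the tabular side of the pipeline:

* :class:`AttackRecord` -- one raw headache-attack log entry, as captured by
  a mobile headache journal;
* :func:`aggregate_attacks` -- collapse a patient's attack log into one
  discrete migbase-schema feature vector (modal location, bucketized median
  duration, per-symptom occurrence probabilities thresholded into flags, ...);
* :func:`encode_sample` / :func:`decode_graph` -- the lossless round-trip
  between feature vectors and RDF-style knowledge graphs, where each
  (attribute, value) pair becomes a ``(sample, has-<attribute>, value)``
  triple and the class label, when present, a single typing triple;
* CSV and Turtle readers/writers for datasets and annotated samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .kb import (
    PREDICATE_PREFIX,
    TYPE_PREDICATE,
    AttributeSpec,
    KnowledgeBase,
    KnowledgeGraph,
    duration_bucket,
    predicate_for,
)

logger = logging.getLogger(__name__)

SET_SEPARATOR = ";"

#: RDF namespace used for Turtle import/export of annotated samples.
NAMESPACE = "http://headachedx.dev/ns#"


def _vocab_list(vocab) -> list[AttributeSpec]:
    if isinstance(vocab, KnowledgeBase):
        return list(vocab.attributes)
    return list(vocab)


# -- feature vectors -------------------------------------------------------


@dataclass
class FeatureVector:
    """A per-patient map attribute -> value token(s), optionally labeled.

    Scalar attributes hold a single token; set-valued attributes hold a
    frozenset of tokens.  ``meta`` carries continuous aggregates (mean/max
    intensity, raw symptom probabilities) that do not fit the discrete
    schema but are useful for data-driven similarity features.
    """

    values: dict
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def validate(self, vocab) -> None:
        for spec in _vocab_list(vocab):
            if spec.name not in self.values:
                continue
            value = self.values[spec.name]
            if spec.is_set_valued:
                bad = set(value) - set(spec.domain)
                if bad:
                    raise ValueError(
                        f"attribute {spec.name!r}: values {sorted(bad)} "
                        f"outside domain"
                    )
            elif value not in spec.domain:
                raise ValueError(
                    f"attribute {spec.name!r}: value {value!r} outside domain"
                )


def _cell_to_value(cell: str, spec: AttributeSpec):
    if spec.is_set_valued:
        return frozenset(cell.split(SET_SEPARATOR)) if cell else frozenset()
    return cell


def _value_to_cell(value, spec: AttributeSpec) -> str:
    if spec.is_set_valued:
        return SET_SEPARATOR.join(sorted(value))
    return str(value)


class LabeledDataset:
    """A labeled cohort of feature vectors, backed by a pandas DataFrame.

    The frame has one column per attribute plus ``label``; set-valued cells
    are ``;``-joined sorted tokens.  ``classes`` fixes the canonical class
    order used for similarity columns, tie-breaking and reports.
    """

    LABEL_COLUMN = "label"

    def __init__(
        self,
        frame: pd.DataFrame,
        vocab,
        classes: Sequence[str] | None = None,
    ):
        vocab = _vocab_list(vocab)
        missing = [a.name for a in vocab if a.name not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing attribute columns {missing}")
        cols = [a.name for a in vocab]
        if self.LABEL_COLUMN in frame.columns:
            cols.append(self.LABEL_COLUMN)
        self.frame = frame[cols].reset_index(drop=True).astype(str)
        self.vocab = tuple(vocab)
        if classes is None:
            classes = sorted(set(self.labels))
        self.classes = list(classes)
        extra = set(self.labels) - set(self.classes)
        if extra:
            raise ValueError(f"labels {sorted(extra)} not in declared classes")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        if self.LABEL_COLUMN not in self.frame.columns:
            return []
        return self.frame[self.LABEL_COLUMN].tolist()

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.vocab]

    def class_counts(self) -> dict[str, int]:
        counts = self.frame[self.LABEL_COLUMN].value_counts()
        return {c: int(counts.get(c, 0)) for c in self.classes}

    def sample(self, i: int) -> FeatureVector:
        row = self.frame.iloc[i]
        values = {
            spec.name: _cell_to_value(row[spec.name], spec) for spec in self.vocab
        }
        label = row.get(self.LABEL_COLUMN)
        return FeatureVector(values, None if label is None else str(label))

    def iter_samples(self) -> Iterator[FeatureVector]:
        for i in range(self.n):
            yield self.sample(i)

    @property
    def samples(self) -> list[FeatureVector]:
        return list(self.iter_samples())

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            self.frame.iloc[list(indices)], self.vocab, self.classes
        )

    def with_vocab(self, vocab) -> "LabeledDataset":
        return LabeledDataset(self.frame, vocab, self.classes)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_vectors(
        cls, vectors: Iterable[FeatureVector], vocab, classes=None
    ) -> "LabeledDataset":
        vocab = _vocab_list(vocab)
        rows = []
        for fv in vectors:
            row = {
                spec.name: _value_to_cell(fv.values[spec.name], spec)
                for spec in vocab
            }
            if fv.label is not None:
                row[cls.LABEL_COLUMN] = fv.label
            rows.append(row)
        return cls(pd.DataFrame(rows), vocab, classes)

    # -- CSV ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def read_dataset_csv(path, kb_or_vocab, classes=None) -> LabeledDataset:
    """Read a one-row-per-patient dataset CSV (``;``-joined set cells)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if classes is None and isinstance(kb_or_vocab, KnowledgeBase):
        classes = kb_or_vocab.class_labels
    ds = LabeledDataset(frame, kb_or_vocab, classes)
    for i, fv in enumerate(ds.iter_samples()):
        try:
            fv.validate(ds.vocab)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return ds


# -- attack records --------------------------------------------------------


@dataclass
class AttackRecord:
    """One raw headache attack, as logged by the patient."""

    patient_id: str
    start_time: float
    end_time: float
    intensity: int
    locations: frozenset = frozenset()
    symptoms: frozenset = frozenset()
    characterization: str = ""
    aura: bool = False
    aura_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("attack end_time before start_time")
        if not 1 <= int(self.intensity) <= 10:
            raise ValueError(f"intensity {self.intensity} outside 1-10 scale")
        self.locations = frozenset(self.locations)
        self.symptoms = frozenset(self.symptoms)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def _modal(tokens: Iterable[str], domain: Sequence[str]) -> str | None:
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    # ties broken by declared domain order (deterministic)
    for candidate in domain:
        if counts.get(candidate) == best:
            return candidate
    return max(counts, key=counts.get)


def _previous_attacks_bucket(n: int) -> str:
    if n <= 4:
        return "a2_4"
    if n <= 9:
        return "a5_9"
    if n <= 19:
        return "a10_19"
    return "a20plus"


def _severity_from_intensity(mean_intensity: float) -> str:
    r = round(mean_intensity)
    if r <= 3:
        return "mild"
    if r <= 7:
        return "moderate"
    return "severe"


def _headache_days_bucket(distinct_days: int, domain: Sequence[str]) -> str:
    if distinct_days == 0:
        token = "none"
    elif distinct_days <= 14:
        token = "d1_14"
    elif distinct_days <= 365:
        token = "d7_365"
    else:
        token = "gt365"
    return token if token in domain else domain[0]


def aggregate_attacks(records: Sequence[AttackRecord], vocab) -> FeatureVector:
    """Aggregate one patient's attack log into a migbase-schema vector.

    Continuous aggregates: mean and maximum intensity, per-symptom occurrence
    probability (kept in ``meta``).  Discrete schema values: severity from
    the rounded mean intensity, modal location and characterisation (ties by
    domain order), the duration bucket of the *median* attack duration, the
    previous-attack-count bucket, and symptom flags obtained by thresholding
    the occurrence probabilities at 0.5.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot aggregate an empty attack log")
    patient_ids = {r.patient_id for r in records}
    if len(patient_ids) > 1:
        raise ValueError(f"records span multiple patients: {sorted(patient_ids)}")

    vocab = _vocab_list(vocab)
    by_name = {a.name: a for a in vocab}
    n = len(records)
    mean_intensity = sum(r.intensity for r in records) / n
    max_intensity = max(r.intensity for r in records)
    symptom_probs: dict[str, float] = {}
    for r in records:
        for s in r.symptoms:
            symptom_probs[s] = symptom_probs.get(s, 0.0) + 1.0
    symptom_probs = {s: c / n for s, c in symptom_probs.items()}

    values: dict = {}
    if "duration" in by_name:
        values["duration"] = duration_bucket(median(r.duration for r in records))
    if "location" in by_name:
        tokens = [t for r in records for t in r.locations]
        values["location"] = (
            _modal(tokens, by_name["location"].domain) or by_name["location"].domain[0]
        )
    if "severity" in by_name:
        values["severity"] = _severity_from_intensity(mean_intensity)
    if "characterisation" in by_name:
        tokens = [r.characterization for r in records if r.characterization]
        values["characterisation"] = (
            _modal(tokens, by_name["characterisation"].domain)
            or by_name["characterisation"].domain[0]
        )
    if "previous_attacks" in by_name:
        values["previous_attacks"] = _previous_attacks_bucket(n)
    if "aura_duration" in by_name:
        aura_durations = [r.aura_duration for r in records if r.aura]
        if not aura_durations:
            values["aura_duration"] = "none"
        else:
            values["aura_duration"] = (
                "day" if median(aura_durations) >= 86400 else "hour"
            )
    if "headache_days" in by_name:
        days = {int(r.start_time // 86400) for r in records}
        values["headache_days"] = _headache_days_bucket(
            len(days), by_name["headache_days"].domain
        )
    if "symptoms" in by_name:
        domain = set(by_name["symptoms"].domain)
        values["symptoms"] = frozenset(
            s for s, p in symptom_probs.items() if p >= 0.5 and s in domain
        )

    fv = FeatureVector(
        values,
        meta={
            "mean_intensity": mean_intensity,
            "max_intensity": max_intensity,
            "symptom_probabilities": dict(sorted(symptom_probs.items())),
        },
    )
    fv.validate(vocab)
    return fv


def read_attacks_csv(path) -> dict[str, list[AttackRecord]]:
    """Read a one-row-per-attack CSV, grouped by patient id."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, list[AttackRecord]] = {}
    for _, row in frame.iterrows():
        rec = AttackRecord(
            patient_id=row["patient_id"],
            start_time=float(row["start_time"]),
            end_time=float(row["end_time"]),
            intensity=int(row["intensity"]),
            locations=frozenset(
                row.get("locations", "").split(SET_SEPARATOR)
                if row.get("locations")
                else []
            ),
            symptoms=frozenset(
                row.get("symptoms", "").split(SET_SEPARATOR)
                if row.get("symptoms")
                else []
            ),
            characterization=row.get("characterization", ""),
            aura=str(row.get("aura", "false")).lower() == "true",
            aura_duration=float(row.get("aura_duration", 0) or 0),
        )
        out.setdefault(rec.patient_id, []).append(rec)
    return out


def write_attacks_csv(records: Iterable[AttackRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "start_time": r.start_time,
            "end_time": r.end_time,
            "intensity": r.intensity,
            "locations": SET_SEPARATOR.join(sorted(r.locations)),
            "symptoms": SET_SEPARATOR.join(sorted(r.symptoms)),
            "characterization": r.characterization,
            "aura": str(bool(r.aura)).lower(),
            "aura_duration": r.aura_duration,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- semantic encoding / decoding -----------------------------------------


def encode_sample(
    fv: FeatureVector, vocab, sample_id: str | None = None
) -> KnowledgeGraph:
    """Encode a feature vector as a knowledge graph.

    One ``(sample, has-<attribute>, value)`` triple per (attribute, value)
    pair; set-valued attributes emit one triple per member.  If the vector
    is labeled, exactly one typing triple ``(sample, is-type, label)`` is
    added.
    """
    fv.validate(vocab)
    root = sample_id if sample_id is not None else "sample-0"
    triples = set()
    for spec in _vocab_list(vocab):
        if spec.name not in fv.values:
            continue
        value = fv.values[spec.name]
        if spec.is_set_valued:
            for member in value:
                triples.add((root, predicate_for(spec.name), member))
        else:
            triples.add((root, predicate_for(spec.name), str(value)))
    if fv.label is not None:
        triples.add((root, TYPE_PREDICATE, fv.label))
    return KnowledgeGraph(frozenset(triples), root)


def decode_graph(g: KnowledgeGraph, vocab) -> FeatureVector:
    """Decode an encoded sample graph back into a feature vector.

    Exact inverse of :func:`encode_sample`: the predicate and object of each
    triple give the attribute and value; a typing triple becomes the label.
    """
    vocab = _vocab_list(vocab)
    by_pred = {predicate_for(a.name): a for a in vocab}
    values: dict = {a.name: set() for a in vocab if a.is_set_valued}
    label = None
    for subj, pred, obj in sorted(g.triples):
        if pred == TYPE_PREDICATE:
            if label is not None and label != obj:
                raise ValueError(
                    f"conflicting typing triples: {label!r} vs {obj!r}"
                )
            label = obj
            continue
        spec = by_pred.get(pred)
        if spec is None:
            raise ValueError(f"unknown predicate {pred!r} in sample graph")
        if obj not in spec.domain:
            raise ValueError(
                f"object {obj!r} outside domain of attribute {spec.name!r}"
            )
        if spec.is_set_valued:
            values[spec.name].add(obj)
        else:
            if spec.name in values:
                raise ValueError(
                    f"multiple values for scalar attribute {spec.name!r}"
                )
            values[spec.name] = obj
    values = {
        k: (frozenset(v) if isinstance(v, set) else v) for k, v in values.items()
    }
    return FeatureVector(values, label)


def strip_typing(g: KnowledgeGraph) -> KnowledgeGraph:
    """Remove all class-label (typing) triples from a graph."""
    triples = frozenset(t for t in g.triples if t[1] != TYPE_PREDICATE)
    return KnowledgeGraph(triples, g.root)


# -- Turtle ----------------------------------------------------------------


def graphs_to_turtle(graphs: Iterable[KnowledgeGraph]) -> str:
    """Serialise knowledge graphs to Turtle under the package namespace."""
    import rdflib

    g = rdflib.Graph()
    ns = rdflib.Namespace(NAMESPACE)
    g.bind("hdx", ns)
    for graph in graphs:
        for s, p, o in sorted(graph.triples):
            g.add((ns[s], ns[p], ns[o]))
    return g.serialize(format="turtle")


def graphs_from_turtle(text: str) -> list[KnowledgeGraph]:
    """Parse Turtle produced by :func:`graphs_to_turtle`.

    Returns one :class:`KnowledgeGraph` per distinct subject, in sorted
    subject order.
    """
    import rdflib

    g = rdflib.Graph()
    g.parse(data=text, format="turtle")

    def localname(term) -> str:
        s = str(term)
        if not s.startswith(NAMESPACE):
            raise ValueError(f"term {s!r} outside the expected namespace")
        return s[len(NAMESPACE):]

    by_subject: dict[str, set] = {}
    for s, p, o in g:
        subj = localname(s)
        by_subject.setdefault(subj, set()).add((subj, localname(p), localname(o)))
    return [
        KnowledgeGraph(frozenset(triples), subj)
        for subj, triples in sorted(by_subject.items())
    ]
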