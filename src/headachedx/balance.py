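"""Class balancing: knowledge-driven over-sampling and data-driven baselines.

Clinical cohorts are heavily imbalanced (cluster headache is an order of
magnitude rarer than migraine), which biases split criteria toward the
majority class.  Five strategies are provided:

* ``none`` -- the untouched dataset;
* ``weights`` -- class-balanced sample weights ``N / (C * n_c)`` fed into
  the split criterion;
* ``smote`` -- synthetic minority samples interpolated between same-class
  nearest neighbours, snapped back onto valid discrete codes;
* ``adasyn`` -- as SMOTE, but synthetics are allocated per minority sample
  in proportion to the share of other-class points among its neighbours
  (more synthetics near the class boundary);
* ``prior-knowledge`` -- minority samples drawn directly from the class
  concepts in the knowledge base; needs no data at all, only the encoded
  diagnostic criteria.

All over-samplers leave the original rows verbatim and first in order, and
top every class up to the majority count.

Discrete features under SMOTE/ADASYN are handled SMOTE-NC-style: ordinal
attributes are integer-coded and rounded after interpolation, nominal
attributes one-hot coded and snapped to the nearest valid one-hot (ties
resolved in favour of the base parent), binary and set-membership flags
rounded at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._encoding import NumericEncoder
from .codec import LabeledDataset
from .kb import KnowledgeBase
from .synth import _as_rng, largest_remainder_counts, sample_from_concept

logger = logging.getLogger(__name__)

TAGS = ("none", "weights", "smote", "adasyn", "prior-knowledge")
#: Short aliases accepted on the command line.
TAG_ALIASES = {"pk": "prior-knowledge"}


@dataclass
class BalancingMethod:
    """Configuration of one balancing strategy."""

    tag: str = "none"
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.tag = TAG_ALIASES.get(self.tag, self.tag)
        if self.tag not in TAGS:
            raise ValueError(f"unknown balancing tag {self.tag!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def class_balanced_weights(ds: LabeledDataset) -> pd.Series:
    """Per-sample weights ``N / (C * n_c)``: equal total mass per class."""
    if ds.n == 0:
        raise ValueError("empty dataset")
    counts = ds.class_counts()
    present = {c: k for c, k in counts.items() if k > 0}
    C = len(present)
    weights = [ds.n / (C * present[y]) for y in ds.labels]
    return pd.Series(weights, name="weight")


def oversample_prior_knowledge(
    ds: LabeledDataset, kb: KnowledgeBase, rng
) -> LabeledDataset:
    """Top minority classes up with samples drawn from their class concepts.

    The appended samples depend only on the knowledge base (never on the
    input feature values) and have zero deviations from their concept by
    construction.  Original rows are preserved verbatim, first in order.
    """
    rng = _as_rng(rng)
    counts = ds.class_counts()
    missing = [c for c in counts if c not in kb.class_labels]
    if missing:
        raise ValueError(f"no concept for classes {missing}")
    target = max(counts.values())
    new_rows = []
    for label in ds.classes:
        concept = kb.concept(label)
        for _ in range(target - counts[label]):
            fv = sample_from_concept(concept, kb.attributes, rng)
            row = {}
            for spec in ds.vocab:
                v = fv.values[spec.name]
                row[spec.name] = ";".join(sorted(v)) if spec.is_set_valued else v
            row[ds.LABEL_COLUMN] = label
            new_rows.append(row)
    if not new_rows:
        return ds
    frame = pd.concat([ds.frame, pd.DataFrame(new_rows)], ignore_index=True)
    return LabeledDataset(frame, ds.vocab, ds.classes)


def _interpolated_rows(
    ds: LabeledDataset,
    encoder: NumericEncoder,
    X: np.ndarray,
    base_indices: np.ndarray,
    neighbor_indices: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    u = rng.random(len(base_indices))
    synth = X[base_indices] + u[:, None] * (X[neighbor_indices] - X[base_indices])
    parents = ds.frame.iloc[base_indices].reset_index(drop=True)
    return encoder.inverse_transform(synth, tie_prefer=parents)


def _same_class_neighbors(
    X: np.ndarray, class_idx: np.ndarray, k: int
) -> np.ndarray:
    """Indices (into the full dataset) of the k nearest same-class rows."""
    k_eff = min(k, len(class_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X[class_idx])
    _, neigh = nn.kneighbors(X[class_idx])
    # drop self (column of zeros distance; ties broken by row index by sklearn)
    out = np.empty((len(class_idx), k_eff), dtype=int)
    for i in range(len(class_idx)):
        row = [j for j in neigh[i] if j != i][:k_eff]
        out[i] = class_idx[np.array(row)]
    return out


def _append_synthetics(ds: LabeledDataset, frames, labels) -> LabeledDataset:
    if not frames:
        return ds
    add = pd.concat(frames, ignore_index=True)
    add[ds.LABEL_COLUMN] = labels
    frame = pd.concat([ds.frame, add], ignore_index=True)
    return LabeledDataset(frame, ds.vocab, ds.classes)


def oversample_smote(
    ds: LabeledDataset, method: BalancingMethod, rng
) -> LabeledDataset:
    """SMOTE over-sampling on the numeric encoding, snapped to valid codes.

    Each synthetic is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` between a
    random minority sample and one of its ``k`` nearest same-class
    neighbours.  A single-sample class is duplicated (with a warning).
    """
    rng = _as_rng(rng)
    encoder = NumericEncoder(ds.vocab)
    X = encoder.transform(ds.frame)
    y = np.asarray(ds.labels)
    counts = ds.class_counts()
    target = max(counts.values())
    frames, labels = [], []
    for label in ds.classes:
        need = target - counts[label]
        if need == 0:
            continue
        if counts[label] == 0:
            raise ValueError(f"class {label!r} has no samples to oversample from")
        class_idx = np.flatnonzero(y == label)
        if len(class_idx) == 1:
            logger.warning(
                "class %r has a single sample; duplicating it %d times",
                label,
                need,
            )
            frames.append(
                ds.frame.iloc[np.repeat(class_idx, need)]
                .drop(columns=[ds.LABEL_COLUMN])
                .reset_index(drop=True)
            )
            labels.extend([label] * need)
            continue
        neighbors = _same_class_neighbors(X, class_idx, method.k_neighbors)
        base_pos = rng.integers(len(class_idx), size=need)
        neigh_col = rng.integers(neighbors.shape[1], size=need)
        base = class_idx[base_pos]
        neigh = neighbors[base_pos, neigh_col]
        frames.append(_interpolated_rows(ds, encoder, X, base, neigh, rng))
        labels.extend([label] * need)
    return _append_synthetics(ds, frames, labels)


def oversample_adasyn(
    ds: LabeledDataset, method: BalancingMethod, rng
) -> LabeledDataset:
    """ADASYN over-sampling: boundary-weighted synthetic allocation.

    The number of synthetics per minority sample is proportional to the
    fraction of other-class points among its ``k`` nearest neighbours in the
    full dataset (largest-remainder rounding of the normalised allocation);
    interpolation itself is SMOTE-style between same-class neighbours.  When
    every minority sample has a purely same-class neighbourhood the
    allocation falls back to uniform.
    """
    rng = _as_rng(rng)
    encoder = NumericEncoder(ds.vocab)
    X = encoder.transform(ds.frame)
    y = np.asarray(ds.labels)
    counts = ds.class_counts()
    target = max(counts.values())
    k_all = min(method.k_neighbors, ds.n - 1)
    nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(X)
    frames, labels = [], []
    for label in ds.classes:
        need = target - counts[label]
        if need == 0:
            continue
        if counts[label] == 0:
            raise ValueError(f"class {label!r} has no samples to oversample from")
        class_idx = np.flatnonzero(y == label)
        if len(class_idx) == 1:
            logger.warning(
                "class %r has a single sample; duplicating it %d times",
                label,
                need,
            )
            frames.append(
                ds.frame.iloc[np.repeat(class_idx, need)]
                .drop(columns=[ds.LABEL_COLUMN])
                .reset_index(drop=True)
            )
            labels.extend([label] * need)
            continue
        _, neigh = nn_all.kneighbors(X[class_idx])
        ratios = np.empty(len(class_idx))
        for i in range(len(class_idx)):
            others = [j for j in neigh[i] if j != class_idx[i]][:k_all]
            ratios[i] = np.mean(y[others] != label)
        if ratios.sum() == 0:
            ratios = np.ones_like(ratios)
        ratios = ratios / ratios.sum()
        alloc = _largest_remainder_alloc(need, ratios)
        neighbors = _same_class_neighbors(X, class_idx, method.k_neighbors)
        base, neigh_pick = [], []
        for i, g in enumerate(alloc):
            for _ in range(g):
                base.append(class_idx[i])
                neigh_pick.append(neighbors[i, rng.integers(neighbors.shape[1])])
        base = np.asarray(base, dtype=int)
        neigh_pick = np.asarray(neigh_pick, dtype=int)
        frames.append(_interpolated_rows(ds, encoder, X, base, neigh_pick, rng))
        labels.extend([label] * need)
    return _append_synthetics(ds, frames, labels)


def _largest_remainder_alloc(total: int, fractions: np.ndarray) -> np.ndarray:
    raw = total * fractions
    alloc = np.floor(raw).astype(int)
    short = total - alloc.sum()
    order = np.argsort(-(raw - alloc), kind="stable")
    alloc[order[:short]] += 1
    return alloc


def apply_balancing(
    ds: LabeledDataset,
    method: BalancingMethod,
    kb: KnowledgeBase | None = None,
    rng=None,
) -> tuple[LabeledDataset, pd.Series | None]:
    """Dispatch a balancing method; returns (dataset, sample_weights)."""
    rng = _as_rng(method.seed if rng is None else rng)
    if method.tag == "none":
        return ds, None
    if method.tag == "weights":
        return ds, class_balanced_weights(ds)
    if method.tag == "smote":
        return oversample_smote(ds, method, rng), None
    if method.tag == "adasyn":
        return oversample_adasyn(ds, method, rng), None
    if kb is None:
        raise ValueError("prior-knowledge balancing requires a knowledge base")
    return oversample_prior_knowledge(ds, kb, rng), None
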