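"""Interpretable classification core: decision trees, feature selection,
hyper-parameter search.

The learner is CART (via scikit-learn) over the package's numeric encoding
of the discrete schema, so every split is a threshold test on an ordinal
code or a one-hot indicator and every root-to-leaf path reads as a rule.
Optional *error-based pruning* follows a held-out contract: a stratified
fraction of the training data is withheld, the tree is grown on the rest,
and any subtree whose replacement by a leaf does not increase held-out error
is collapsed (bottom-up).

Feature selection is a wrapper genetic algorithm over binary attribute
masks, with internal stratified-CV accuracy as fitness; hyper-parameters are
tuned by exhaustive grid search.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from ._encoding import NumericEncoder
from .codec import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_TREE_PARAMS: dict = {
    "criterion": "gini",
    "max_depth": None,
    "min_samples_split": 2,
    "pruning": False,
    "prune_fraction": 0.2,
}

DEFAULT_GRID: dict = {
    "criterion": ["gini", "entropy"],
    "max_depth": [3, 5, 7, None],
    "min_samples_split": [2, 5],
    "pruning": [False, True],
}


def drop_constant_features(ds: LabeledDataset) -> tuple[LabeledDataset, list[str]]:
    """Remove attributes taking a single value across all samples.

    Real questionnaire exports routinely contain such columns (symptoms
    nobody reported); they carry no signal and inflate the search space.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    removed = [
        name for name in ds.attribute_names if ds.frame[name].nunique() == 1
    ]
    if len(removed) == len(ds.attribute_names):
        raise ValueError("all features are constant; nothing learnable")
    if not removed:
        return ds, []
    kept = [a for a in ds.vocab if a.name not in set(removed)]
    return LabeledDataset(ds.frame, kept, ds.classes), removed


# -- tree model ------------------------------------------------------------


class TreeModel:
    """A fitted decision tree with optional collapsed (pruned) subtrees.

    Prediction routes each encoded sample through the tree, stopping early
    at collapsed nodes, and predicts the (weight-) majority training class
    of the stopping node.
    """

    def __init__(
        self,
        estimator: DecisionTreeClassifier | None,
        encoder: NumericEncoder,
        classes: list[str],
        collapsed: frozenset = frozenset(),
        constant: str | None = None,
    ):
        self._est = estimator
        self.encoder = encoder
        self.classes = classes
        self.collapsed = collapsed
        self.constant = constant

    # -- structure ---------------------------------------------------------

    def _is_leaf(self, node: int) -> bool:
        t = self._est.tree_
        return t.children_left[node] == -1 or node in self.collapsed

    def _walk(self):
        """Yield (node, depth) over the effective (post-pruning) tree."""
        t = self._est.tree_
        stack = [(0, 0)]
        while stack:
            node, depth = stack.pop()
            yield node, depth
            if not self._is_leaf(node):
                stack.append((t.children_right[node], depth + 1))
                stack.append((t.children_left[node], depth + 1))

    @property
    def node_count(self) -> int:
        if self._est is None:
            return 1
        return sum(1 for _ in self._walk())

    @property
    def depth(self) -> int:
        if self._est is None:
            return 0
        return max(d for _, d in self._walk())

    def _node_class(self, node: int) -> str:
        value = self._est.tree_.value[node][0]
        return str(self._est.classes_[int(np.argmax(value))])

    # -- prediction --------------------------------------------------------

    def predict_encoded(self, X: np.ndarray) -> list[str]:
        if self.constant is not None:
            return [self.constant] * len(X)
        t = self._est.tree_
        out = []
        for row in np.asarray(X, dtype=float):
            node = 0
            while not self._is_leaf(node):
                if row[t.feature[node]] <= t.threshold[node]:
                    node = t.children_left[node]
                else:
                    node = t.children_right[node]
            out.append(self._node_class(node))
        return out

    def predict(self, data, extra: np.ndarray | None = None) -> list[str]:
        """Predict labels for a dataset or frame over the training vocabulary."""
        frame = data.frame if isinstance(data, LabeledDataset) else data
        try:
            X = self.encoder.transform(frame)
        except KeyError as exc:
            raise ValueError(f"sample missing attribute {exc}") from exc
        if extra is not None:
            X = np.hstack([X, np.asarray(extra, dtype=float)])
        return self.predict_encoded(X)

    # -- export ------------------------------------------------------------

    def export_text(self) -> str:
        """Indented-text rules, one line per node."""
        if self.constant is not None:
            return f"predict {self.constant}\n"
        t = self._est.tree_
        names = self.encoder.columns
        lines = []

        def emit(node: int, depth: int, prefix: str) -> None:
            indent = "  " * depth
            if self._is_leaf(node):
                lines.append(f"{indent}{prefix}predict {self._node_class(node)}")
                return
            name = names[t.feature[node]]
            thr = t.threshold[node]
            lines.append(f"{indent}{prefix}if {name} <= {thr:.3f}:")
            emit(t.children_left[node], depth + 1, "")
            lines.append(f"{indent}else:  # {name} > {thr:.3f}")
            emit(t.children_right[node], depth + 1, "")

        emit(0, 0, "")
        return "\n".join(lines) + "\n"

    def export_dot(self) -> str:
        """Graphviz DOT source of the effective tree."""
        lines = ["digraph tree {", "  node [shape=box];"]
        if self.constant is not None:
            lines.append(f'  0 [label="predict {self.constant}"];')
        else:
            t = self._est.tree_
            names = self.encoder.columns
            for node, _ in self._walk():
                if self._is_leaf(node):
                    label = f"predict {self._node_class(node)}"
                else:
                    label = f"{names[t.feature[node]]} <= {t.threshold[node]:.3f}"
                lines.append(f'  {node} [label="{label}"];')
                if not self._is_leaf(node):
                    lines.append(f"  {node} -> {t.children_left[node]};")
                    lines.append(f"  {node} -> {t.children_right[node]};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def _merge_params(params: Mapping | None) -> dict:
    merged = dict(DEFAULT_TREE_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_TREE_PARAMS)
        if unknown:
            raise ValueError(f"unknown tree parameters {sorted(unknown)}")
        merged.update(params)
    return merged


def fit_tree(
    ds: LabeledDataset,
    params: Mapping | None = None,
    sample_weight: Sequence[float] | None = None,
    seed: int = 0,
    attributes: Sequence[str] | None = None,
    extra: np.ndarray | None = None,
    extra_names: Sequence[str] = (),
) -> TreeModel:
    """Fit a CART decision tree on the encoded dataset.

    ``attributes`` restricts the attribute set (feature-selection masks);
    ``extra`` appends precomputed numeric feature columns (e.g. similarity
    blocks) named by ``extra_names``.  With ``pruning`` enabled, a stratified
    ``prune_fraction`` of the rows is withheld and used for reduced-error
    pruning.  A single-class dataset yields a single-leaf tree (warned);
    ``max_depth`` 0 a majority-vote stump.
    """
    params = _merge_params(params)
    encoder = NumericEncoder(ds.vocab, attributes=attributes)
    X = encoder.transform(ds.frame)
    if extra is not None:
        extra = np.asarray(extra, dtype=float)
        names = list(extra_names) or [f"extra_{i}" for i in range(extra.shape[1])]
        X = np.hstack([X, extra])
        encoder.columns = encoder.columns + names
    y = np.asarray(ds.labels)
    if sample_weight is not None:
        sample_weight = np.asarray(sample_weight, dtype=float)
        if len(sample_weight) != len(y):
            raise ValueError("one weight per sample required")
        if np.any(sample_weight <= 0):
            raise ValueError("sample weights must be positive")

    classes = list(ds.classes)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class dataset; fitting a single-leaf tree")
        return TreeModel(None, encoder, classes, constant=str(y[0]))
    if params["max_depth"] == 0:
        masses = pd.Series(
            sample_weight if sample_weight is not None else np.ones(len(y))
        ).groupby(y).sum()
        majority = masses.sort_index().idxmax()
        # idxmax on the sorted index ties toward the alphabetically first
        # label; re-resolve ties in canonical class order
        best = masses.max()
        for c in classes:
            if masses.get(c, 0) == best:
                majority = c
                break
        return TreeModel(None, encoder, classes, constant=str(majority))

    def make_estimator():
        return DecisionTreeClassifier(
            criterion=params["criterion"],
            max_depth=params["max_depth"],
            min_samples_split=params["min_samples_split"],
            random_state=seed,
        )

    if not params["pruning"]:
        est = make_estimator().fit(X, y, sample_weight=sample_weight)
        return TreeModel(est, encoder, classes)

    frac = params["prune_fraction"]
    idx = np.arange(len(y))
    # stratified held-out pruning set; fall back to no pruning when a class
    # is too small to stratify
    try:
        grow_idx, prune_idx = train_test_split(
            idx, test_size=frac, stratify=y, random_state=seed
        )
    except ValueError:
        logger.warning("cannot stratify pruning split; pruning skipped")
        est = make_estimator().fit(X, y, sample_weight=sample_weight)
        return TreeModel(est, encoder, classes)
    sw = None if sample_weight is None else sample_weight[grow_idx]
    if len(np.unique(y[grow_idx])) < 2:
        warnings.warn("single-class grow set; fitting a single-leaf tree")
        return TreeModel(None, encoder, classes, constant=str(y[grow_idx][0]))
    est = make_estimator().fit(X[grow_idx], y[grow_idx], sample_weight=sw)
    collapsed = _reduced_error_prune(est, X[prune_idx], y[prune_idx])
    return TreeModel(est, encoder, classes, collapsed=collapsed)


def _reduced_error_prune(
    est: DecisionTreeClassifier, X_prune: np.ndarray, y_prune: np.ndarray
) -> frozenset:
    """Bottom-up reduced-error pruning against a held-out set.

    Collapses every internal node whose replacement by a majority leaf does
    not increase the number of held-out errors.  Returns the set of
    collapsed node ids.  Never increases held-out error or node count.
    """
    t = est.tree_
    n_nodes = t.node_count
    node_indicator = est.decision_path(X_prune)
    majority = np.argmax(t.value[:, 0, :], axis=1)
    y_codes = np.searchsorted(est.classes_, y_prune)

    errors_as_leaf = np.zeros(n_nodes, dtype=int)
    reach = np.zeros(n_nodes, dtype=int)
    rows, cols = node_indicator.nonzero()
    for sample, node in zip(rows, cols):
        reach[node] += 1
        if y_codes[sample] != majority[node]:
            errors_as_leaf[node] += 1

    subtree_error = np.zeros(n_nodes, dtype=int)
    collapsed = set()
    # children always have larger ids than their parent in sklearn trees,
    # so reverse id order is a valid bottom-up order
    for node in range(n_nodes - 1, -1, -1):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            subtree_error[node] = errors_as_leaf[node]
            continue
        child_err = subtree_error[left] + subtree_error[right]
        if errors_as_leaf[node] <= child_err:
            collapsed.add(node)
            subtree_error[node] = errors_as_leaf[node]
        else:
            subtree_error[node] = child_err
    return frozenset(collapsed)


def predict(tree: TreeModel, samples, extra: np.ndarray | None = None) -> list[str]:
    """Route samples through a fitted tree (module-level convenience)."""
    return tree.predict(samples, extra=extra)


# -- cross-validated accuracy (internal helper) ---------------------------


def _cv_accuracy(
    ds: LabeledDataset,
    params: Mapping | None,
    folds: int,
    seed: int,
    attributes: Sequence[str] | None = None,
) -> float:
    y = np.asarray(ds.labels)
    min_class = min(np.unique(y, return_counts=True)[1])
    k = max(2, min(folds, int(min_class)))
    if k < folds:
        logger.warning("reducing CV folds from %d to %d (small class)", folds, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = fit_tree(
            ds.subset(train_idx), params, seed=seed, attributes=attributes
        )
        pred = model.predict(ds.frame.iloc[test_idx])
        correct += int(np.sum(np.asarray(pred) == y[test_idx]))
    return correct / len(y)


# -- genetic feature selection --------------------------------------------


@dataclass
class GAConfig:
    """Wrapper-GA configuration for binary feature masks."""

    population: int = 50
    generations: int = 20
    crossover_prob: float = 0.5
    mutation_prob: float | None = None  # default 1 / n_features
    fitness_folds: int = 3
    elitism: int = 1
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob outside [0, 1]")
        if self.mutation_prob is not None and not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob outside [0, 1]")


def _better(cand: tuple, incumbent: tuple | None) -> bool:
    """Mask preference: higher fitness, then fewer features, then lexicographic."""
    if incumbent is None:
        return True
    f1, m1 = cand
    f0, m0 = incumbent
    if f1 != f0:
        return f1 > f0
    if sum(m1) != sum(m0):
        return sum(m1) < sum(m0)
    return m1 < m0


def genetic_feature_selection(
    ds: LabeledDataset,
    tree_params: Mapping | None = None,
    ga: GAConfig | None = None,
) -> np.ndarray:
    """Search attribute masks by a genetic algorithm; return the best mask.

    Fitness is mean stratified-CV accuracy of the tree restricted to the
    masked attributes; the all-zero mask scores 0 and is never returned.
    The best mask ever evaluated (including the initial population) is
    returned, with ties broken toward fewer features, then lexicographically.
    Deterministic given ``ga.seed``.
    """
    ga = ga or GAConfig()
    names = ds.attribute_names
    n = len(names)
    if n == 0:
        raise ValueError("empty feature set")
    rng = np.random.default_rng(ga.seed)
    p_mut = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / n
    cache: dict[tuple, float] = {}

    def fitness(mask: tuple) -> float:
        if mask not in cache:
            if not any(mask):
                cache[mask] = 0.0
            else:
                selected = [names[i] for i in range(n) if mask[i]]
                cache[mask] = _cv_accuracy(
                    ds, tree_params, ga.fitness_folds, ga.seed, selected
                )
        return cache[mask]

    population = [
        tuple(int(b) for b in rng.integers(0, 2, size=n))
        for _ in range(ga.population)
    ]
    best: tuple | None = None
    for mask in population:
        if _better((fitness(mask), mask), best):
            best = (fitness(mask), mask)

    for _ in range(ga.generations):
        fits = np.array([fitness(m) for m in population])
        elite = [
            population[i]
            for i in np.argsort(-fits, kind="stable")[: ga.elitism]
        ]
        offspring = list(elite)
        while len(offspring) < ga.population:
            def pick():
                contenders = rng.integers(len(population), size=ga.tournament)
                return population[int(contenders[np.argmax(fits[contenders])])]

            a, b = list(pick()), list(pick())
            if rng.random() < ga.crossover_prob:
                swap = rng.random(n) < 0.5
                for i in np.flatnonzero(swap):
                    a[i], b[i] = b[i], a[i]
            for child in (a, b):
                if len(offspring) >= ga.population:
                    break
                flips = rng.random(n) < p_mut
                genome = tuple(
                    int(bit) ^ int(fl) for bit, fl in zip(child, flips)
                )
                offspring.append(genome)
        population = offspring
        for mask in population:
            if _better((fitness(mask), mask), best):
                best = (fitness(mask), mask)

    return np.asarray(best[1], dtype=bool)


# -- grid search -----------------------------------------------------------


def grid_search_cv(
    ds: LabeledDataset,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Exhaustive hyper-parameter search by mean stratified-CV accuracy.

    Every combination of the grid is evaluated; returns the best parameter
    dict (ties to the first combination in deterministic enumeration order)
    together with the full results list.
    """
    grid = dict(grid) if grid else dict(DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyper-parameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    keys = list(grid)
    results = []
    best: tuple[dict, float] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        acc = _cv_accuracy(ds, params, folds, seed)
        results.append((params, acc))
        if best is None or acc > best[1]:
            best = (params, acc)
    return best[0], results
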