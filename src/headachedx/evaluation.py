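"""Evaluation protocol: accuracy, Cohen's kappa, per-class sensitivity and
specificity, stratified k-fold prediction, repeated simulations and paired
bootstrap significance tests.

Accuracy is the fraction of correct out-of-fold predictions,
``(1/N) * sum 1[y_hat_i = y_i]``.  Cohen's kappa corrects agreement for
chance, ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed
agreement (= accuracy) and ``p_e = (1/N^2) * sum_c n_hat_c * n_c`` the
agreement expected when labels are assigned at random with the observed
marginals -- the metric of choice under heavy class imbalance.

``run_simulations`` repeats the full cross-validated pipeline (re-seeded
fold splits and, when a cohort generator is supplied, freshly generated
cohorts) and reports means and standard deviations per technique; paired
bootstrap tests on per-simulation differences decide which differences from
the baseline are significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .balance import TAG_ALIASES, BalancingMethod, apply_balancing
from .codec import LabeledDataset
from .kb import KnowledgeBase
from .kernels import (
    WFConfig,
    build_class_vectors,
    vector_similarity_block,
    wf_similarity_block,
)
from .pipeline import TreeModel, fit_tree

logger = logging.getLogger(__name__)


# -- prediction sets and closed-form metrics ------------------------------


@dataclass
class PredictionSet:
    """True and predicted labels over a fixed class set."""

    y: list[str]
    y_hat: list[str]
    classes: list[str]

    def __post_init__(self) -> None:
        self.y = [str(v) for v in self.y]
        self.y_hat = [str(v) for v in self.y_hat]
        if len(self.y) != len(self.y_hat):
            raise ValueError("y and y_hat length mismatch")
        bad = (set(self.y) | set(self.y_hat)) - set(self.classes)
        if bad:
            raise ValueError(f"labels {sorted(bad)} outside the class set")

    @property
    def n(self) -> int:
        return len(self.y)


def accuracy(ps: PredictionSet) -> float:
    """Fraction of samples with correct prediction."""
    if ps.n == 0:
        raise ValueError("empty prediction set")
    return sum(a == b for a, b in zip(ps.y, ps.y_hat)) / ps.n


def cohen_kappa(ps: PredictionSet) -> float:
    """Unweighted Cohen's kappa: chance-corrected agreement."""
    p_o = accuracy(ps)
    n = ps.n
    p_e = sum(
        ps.y_hat.count(c) * ps.y.count(c) for c in ps.classes
    ) / (n * n)
    if p_e == 1.0:
        logger.warning("expected agreement p_e = 1; kappa defined as 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def sensitivity_specificity(ps: PredictionSet, cls: str) -> tuple[float, float]:
    """One-vs-rest true-positive and true-negative rate for one class.

    Zero denominators yield 0 with a warning (kept, not dropped, so report
    shapes stay rectangular).
    """
    if cls not in ps.classes:
        raise ValueError(f"unknown class {cls!r}")
    tp = sum(1 for a, b in zip(ps.y, ps.y_hat) if a == cls and b == cls)
    fn = sum(1 for a, b in zip(ps.y, ps.y_hat) if a == cls and b != cls)
    fp = sum(1 for a, b in zip(ps.y, ps.y_hat) if a != cls and b == cls)
    tn = ps.n - tp - fn - fp
    if tp + fn == 0:
        logger.warning("class %r absent from y; sensitivity reported as 0", cls)
        sens = 0.0
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        logger.warning("no negatives for class %r; specificity reported as 0", cls)
        spec = 0.0
    else:
        spec = tn / (tn + fp)
    return sens, spec


# -- cross-validated pipeline ---------------------------------------------


@dataclass
class PipelineConfig:
    """What the per-fold training pipeline does.

    ``balance`` is one of none/weights/smote/adasyn/prior-knowledge (pk);
    ``features`` optionally appends similarity columns ("wf", "rbf",
    "cosine") either on top of the original attributes (mode "augment") or
    replacing them (mode "only", the pure-similarity rows of the feature
    study).  Balancing and data-driven class vectors are fitted on training
    folds only; the knowledge-driven WL similarities depend only on the
    knowledge base and are leakage-free by construction.
    """

    balance: str = "none"
    k_neighbors: int = 5
    tree_params: Mapping | None = None
    kb: KnowledgeBase | None = None
    features: str | None = None
    feature_mode: str = "augment"
    wf: WFConfig = field(default_factory=WFConfig)
    gamma: float | None = None
    class_vector_mode: str = "centroid"

    def __post_init__(self) -> None:
        self.balance = TAG_ALIASES.get(self.balance, self.balance)
        if self.features not in (None, "wf", "rbf", "cosine"):
            raise ValueError(f"unknown feature metric {self.features!r}")
        if self.feature_mode not in ("augment", "only"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if self.balance == "prior-knowledge" and self.kb is None:
            raise ValueError("prior-knowledge balancing requires kb")
        if self.features == "wf" and self.kb is None:
            raise ValueError("WL similarity features require kb")


def _fold_model(
    train: LabeledDataset, config: PipelineConfig, rng: np.random.Generator, seed: int
) -> tuple[TreeModel, object]:
    """Fit the configured pipeline on one training fold.

    Returns the tree plus whatever state is needed to featurise test rows
    (class vectors for rbf/cosine; None for wf, which is data-independent).
    """
    method = BalancingMethod(config.balance, config.k_neighbors)
    balanced, weights = apply_balancing(train, method, kb=config.kb, rng=rng)

    extra = None
    extra_names: list[str] = []
    state = None
    if config.features == "wf":
        block = wf_similarity_block(balanced, config.kb, config.wf)
        extra, extra_names = block.matrix, block.column_names
    elif config.features in ("rbf", "cosine"):
        state = build_class_vectors(balanced, config.class_vector_mode)
        block = vector_similarity_block(
            balanced,
            config.features,
            class_vectors=state,
            gamma=config.gamma,
        )
        extra, extra_names = block.matrix, block.column_names

    attributes = [] if config.feature_mode == "only" and extra is not None else None
    model = fit_tree(
        balanced,
        config.tree_params,
        sample_weight=weights,
        seed=seed,
        attributes=attributes,
        extra=extra,
        extra_names=extra_names,
    )
    return model, state


def _featurise_test(
    test: LabeledDataset, config: PipelineConfig, state
) -> np.ndarray | None:
    if config.features == "wf":
        return wf_similarity_block(test, config.kb, config.wf).matrix
    if config.features in ("rbf", "cosine"):
        return vector_similarity_block(
            test, config.features, class_vectors=state, gamma=config.gamma
        ).matrix
    return None


def stratified_kfold_predict(
    ds: LabeledDataset,
    k: int,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PredictionSet:
    """Out-of-fold predictions from stratified k-fold cross-validation.

    Every pipeline stage that learns from data (over-sampling, class
    vectors, the tree) is fitted on the training folds only; the held-out
    fold is never touched before prediction.  ``k`` is reduced (with a
    warning) when a class has fewer than ``k`` members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or PipelineConfig()
    y = np.asarray(ds.labels)
    min_class = int(min(np.unique(y, return_counts=True)[1]))
    if min_class < k:
        logger.warning("reducing folds from %d to %d (smallest class)", k, min_class)
        k = max(2, min_class)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_hat = np.empty(len(y), dtype=object)
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(y)), y)
    ):
        rng = np.random.default_rng([seed, fold])
        model, state = _fold_model(ds.subset(train_idx), config, rng, seed)
        test = ds.subset(test_idx)
        extra = _featurise_test(test, config, state)
        y_hat[test_idx] = model.predict(test, extra=extra)
    return PredictionSet(list(y), list(y_hat), list(ds.classes))


# -- repeated simulations --------------------------------------------------


@dataclass
class MetricReport:
    """Per-technique metric samples across simulations, plus summaries."""

    samples: dict  # technique -> metric -> np.ndarray of per-sim values
    classes: list[str]
    n_sims: int

    def mean(self, technique: str, metric: str) -> float:
        return float(np.mean(self.samples[technique][metric]))

    def sd(self, technique: str, metric: str) -> float:
        return float(np.std(self.samples[technique][metric], ddof=0))

    @property
    def techniques(self) -> list[str]:
        return list(self.samples)

    @property
    def metrics(self) -> list[str]:
        first = next(iter(self.samples.values()))
        return list(first)

    def to_frame(self) -> pd.DataFrame:
        """Numeric summary: rows = technique, columns = metric mean and sd."""
        rows = {}
        for t in self.techniques:
            row = {}
            for m in self.metrics:
                row[f"{m}_mean"] = self.mean(t, m)
                row[f"{m}_sd"] = self.sd(t, m)
            rows[t] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_table(
        self,
        baseline: str = "none",
        n_boot: int = 2000,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Render "mean±sd" cells with +/- significance marks vs baseline.

        A cell is marked ``+`` (``-``) when the technique's metric is higher
        (lower) than the baseline's with a paired-bootstrap p <= alpha.
        """
        rows = {}
        for t in self.techniques:
            row = {}
            for m in self.metrics:
                cell = f"{self.mean(t, m):.4f}±{self.sd(t, m):.4f}"
                if t != baseline and baseline in self.samples:
                    res = bootstrap_compare(
                        self.samples[t][m],
                        self.samples[baseline][m],
                        n_boot=n_boot,
                        seed=seed,
                        alpha=alpha,
                    )
                    if res.significant:
                        cell += "+" if res.observed_difference > 0 else "-"
                row[m] = cell
            rows[t] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def run_simulations(
    source: LabeledDataset | Callable[[int], LabeledDataset],
    techniques: Sequence[str],
    n_sims: int,
    seed: int = 0,
    k: int = 5,
    base_config: PipelineConfig | None = None,
) -> MetricReport:
    """Repeat the cross-validated pipeline and collect metric distributions.

    Simulation ``s`` re-seeds the fold split with ``seed + s`` and, when
    ``source`` is a generator callable, draws a fresh cohort from it with
    the same seed.  For each technique the out-of-fold accuracy, kappa and
    per-class sensitivity/specificity are recorded.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    techniques = [TAG_ALIASES.get(t, t) for t in techniques]
    base = base_config or PipelineConfig()
    samples: dict = {}
    classes: list[str] | None = None
    for s in range(n_sims):
        sim_seed = seed + s
        ds = source(sim_seed) if callable(source) else source
        if classes is None:
            classes = list(ds.classes)
        for tech in techniques:
            config = PipelineConfig(
                balance=tech,
                k_neighbors=base.k_neighbors,
                tree_params=base.tree_params,
                kb=base.kb,
                features=base.features,
                feature_mode=base.feature_mode,
                wf=base.wf,
                gamma=base.gamma,
                class_vector_mode=base.class_vector_mode,
            )
            ps = stratified_kfold_predict(ds, k, config, seed=sim_seed)
            store = samples.setdefault(
                tech,
                {
                    m: np.zeros(n_sims)
                    for m in ["accuracy", "kappa"]
                    + [f"sensitivity_{c}" for c in classes]
                    + [f"specificity_{c}" for c in classes]
                },
            )
            store["accuracy"][s] = accuracy(ps)
            store["kappa"][s] = cohen_kappa(ps)
            for c in classes:
                sens, spec = sensitivity_specificity(ps, c)
                store[f"sensitivity_{c}"][s] = sens
                store[f"specificity_{c}"][s] = spec
    return MetricReport(samples, classes or [], n_sims)


# -- bootstrap significance -----------------------------------------------


@dataclass
class BootstrapResult:
    """Two-sided paired bootstrap test of a mean metric difference."""

    observed_difference: float
    n_boot: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def bootstrap_compare(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Paired bootstrap on per-simulation differences ``d_s = a_s - b_s``.

    The per-simulation differences are resampled with replacement; the
    two-sided p-value is the fraction of resampled means at least as far
    from the observed mean as the observed mean is from zero (shifting the
    resampled distribution to the null), with add-one smoothing.  Swapping
    ``a`` and ``b`` leaves the p-value unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two paired observations")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d = a - b
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(d), size=(n_boot, len(d)))
    means = d[idx].mean(axis=1)
    extreme = int(np.sum(np.abs(means - observed) >= abs(observed)))
    p = (extreme + 1) / (n_boot + 1)
    return BootstrapResult(observed, n_boot, float(min(p, 1.0)), alpha)
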