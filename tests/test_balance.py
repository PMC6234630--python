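"""Over-sampling contracts: prior-knowledge, SMOTE, ADASYN, sample weights."""

import numpy as np
import pandas as pd
import pytest

from headachedx import (
    BalancingMethod,
    LabeledDataset,
    class_balanced_weights,
    count_deviations,
    oversample_adasyn,
    oversample_prior_knowledge,
    oversample_smote,
)
from headachedx.kb import AttributeSpec


def toy_dataset(codes_by_class, domain_size=30):
    """1-D ordinal dataset: class -> list of integer codes."""
    domain = tuple(f"v{i:02d}" for i in range(domain_size))
    vocab = (AttributeSpec("x", "ordinal-categorical", domain),)
    rows = [
        {"x": domain[code], "label": label}
        for label, codes in codes_by_class.items()
        for code in codes
    ]
    return (
        LabeledDataset(pd.DataFrame(rows), vocab, classes=list(codes_by_class)),
        domain,
    )


class TestPriorKnowledge:
    def test_equalises_counts_and_preserves_originals(self, kb, noisy_cohort):
        out = oversample_prior_knowledge(noisy_cohort, kb, np.random.default_rng(0))
        assert out.class_counts() == {c: 609 for c in kb.class_labels}
        assert out.n == 1827
        assert out.frame.iloc[: noisy_cohort.n].equals(noisy_cohort.frame)

    def test_appended_samples_have_zero_deviations(self, kb, noisy_cohort):
        out = oversample_prior_knowledge(noisy_cohort, kb, np.random.default_rng(1))
        for i in range(noisy_cohort.n, out.n):
            fv = out.sample(i)
            assert count_deviations(fv, kb.concept(fv.label))[0] == 0

    def test_already_balanced_dataset_unchanged(self, kb, noisy_cohort):
        balanced = oversample_prior_knowledge(
            noisy_cohort, kb, np.random.default_rng(2)
        )
        again = oversample_prior_knowledge(balanced, kb, np.random.default_rng(3))
        assert again.frame.equals(balanced.frame)

    def test_never_reads_input_feature_values(self, kb, noisy_cohort):
        """Garbling every feature cell must not change the appended rows."""
        garbled_frame = noisy_cohort.frame.copy()
        for spec in noisy_cohort.vocab:
            garbled_frame[spec.name] = (
                "" if spec.is_set_valued else spec.domain[0]
            )
        garbled = LabeledDataset(garbled_frame, noisy_cohort.vocab,
                                 noisy_cohort.classes)
        out_clean = oversample_prior_knowledge(
            noisy_cohort, kb, np.random.default_rng(7)
        )
        out_garbled = oversample_prior_knowledge(garbled, kb, np.random.default_rng(7))
        appended_clean = out_clean.frame.iloc[noisy_cohort.n:].reset_index(drop=True)
        appended_garbled = out_garbled.frame.iloc[noisy_cohort.n:].reset_index(
            drop=True
        )
        assert appended_clean.equals(appended_garbled)

    def test_class_without_concept_rejected(self, kb, noisy_cohort):
        bad = LabeledDataset(
            noisy_cohort.frame.assign(label="sinusitis"),
            noisy_cohort.vocab,
            ["sinusitis"],
        )
        with pytest.raises(ValueError, match="no concept"):
            oversample_prior_knowledge(bad, kb, np.random.default_rng(0))


class TestSmote:
    def test_identical_minority_pair_yields_identical_synthetics(self):
        ds, domain = toy_dataset({"maj": [0, 1, 2, 3, 4, 5], "min": [9, 9]})
        out = oversample_smote(ds, BalancingMethod("smote"), np.random.default_rng(0))
        synthetic = out.frame.iloc[ds.n:]
        assert (synthetic["x"] == domain[9]).all()
        assert (synthetic["label"] == "min").all()

    def test_ordinal_interpolation_stays_between_parents(self):
        ds, domain = toy_dataset({"maj": [20] * 8, "min": [1, 3]})
        out = oversample_smote(ds, BalancingMethod("smote"), np.random.default_rng(1))
        synthetic = out.frame.iloc[ds.n:]["x"]
        assert set(synthetic) <= {domain[1], domain[2], domain[3]}

    def test_counts_equal_majority_and_originals_first(self, kb, noisy_cohort):
        out = oversample_smote(
            noisy_cohort, BalancingMethod("smote"), np.random.default_rng(2)
        )
        counts = out.class_counts()
        assert len(set(counts.values())) == 1
        assert out.frame.iloc[: noisy_cohort.n].equals(noisy_cohort.frame)

    def test_singleton_minority_duplicated_with_warning(self, caplog):
        ds, domain = toy_dataset({"maj": [0, 1, 2], "min": [9]})
        with caplog.at_level("WARNING"):
            out = oversample_smote(
                ds, BalancingMethod("smote"), np.random.default_rng(0)
            )
        assert "single sample" in caplog.text
        assert (out.frame.iloc[ds.n:]["x"] == domain[9]).all()

    def test_reproducible_given_seed(self, kb, noisy_cohort):
        runs = [
            oversample_smote(
                noisy_cohort, BalancingMethod("smote"), np.random.default_rng(5)
            ).frame
            for _ in range(2)
        ]
        assert runs[0].equals(runs[1])


class TestAdasyn:
    def test_allocation_concentrates_on_boundary_point(self):
        # minority m1 (code 0) has purely-majority neighbours; the tight
        # minority cluster at codes 14-16 has purely-minority neighbourhoods,
        # so every synthetic must be allocated to m1 (allocation oracle:
        # r = (1,0,0,0) -> all of the deficit).
        ds, domain = toy_dataset(
            {"maj": [1, 2, 25, 26, 27, 28], "min": [0, 14, 15, 16]}
        )
        out = oversample_adasyn(
            ds, BalancingMethod("adasyn", k_neighbors=2), np.random.default_rng(0)
        )
        synthetic = out.frame.iloc[ds.n:]["x"]
        assert len(synthetic) == 2
        # interpolations from m1 toward its same-class neighbours lie in
        # codes 0..15; none may be a pure within-cluster interpolation
        codes = [int(v[1:]) for v in synthetic]
        assert all(c <= 15 for c in codes)
        assert any(c < 14 for c in codes)

    def test_largest_remainder_allocation(self):
        from headachedx.balance import _largest_remainder_alloc

        alloc = _largest_remainder_alloc(5, np.array([0.5, 0.3, 0.2]))
        assert alloc.tolist() == [3, 1, 1]
        assert _largest_remainder_alloc(7, np.array([1.0, 0.0])).tolist() == [7, 0]

    def test_uniform_fallback_when_no_majority_neighbours(self):
        # the two classes are far apart: every minority neighbourhood is
        # purely same-class, so the allocation degrades to uniform and the
        # output still balances the counts (SMOTE-like behaviour)
        ds, _ = toy_dataset({"maj": [0, 1, 2, 3], "min": [25, 26, 27]})
        out = oversample_adasyn(
            ds, BalancingMethod("adasyn", k_neighbors=2), np.random.default_rng(1)
        )
        assert len(set(out.class_counts().values())) == 1

    def test_counts_equal_after_balancing(self, kb, noisy_cohort):
        out = oversample_adasyn(
            noisy_cohort, BalancingMethod("adasyn"), np.random.default_rng(3)
        )
        assert len(set(out.class_counts().values())) == 1
        assert out.frame.iloc[: noisy_cohort.n].equals(noisy_cohort.frame)


class TestWeights:
    def test_two_class_arithmetic(self):
        ds, _ = toy_dataset({"a": list(range(15)) * 5, "b": list(range(25))})
        weights = class_balanced_weights(ds)
        assert ds.class_counts() == {"a": 75, "b": 25}
        np.testing.assert_allclose(weights[:75], 100 / (2 * 75))
        np.testing.assert_allclose(weights[75:], 2.0)
        assert weights.sum() == pytest.approx(ds.n)

    def test_balanced_dataset_gets_unit_weights(self):
        ds, _ = toy_dataset({"a": [0, 1, 2], "b": [5, 6, 7]})
        np.testing.assert_allclose(class_balanced_weights(ds), 1.0)

    def test_weighted_class_masses_equal(self, noisy_cohort):
        weights = np.asarray(class_balanced_weights(noisy_cohort))
        labels = np.asarray(noisy_cohort.labels)
        masses = {c: weights[labels == c].sum() for c in noisy_cohort.classes}
        np.testing.assert_allclose(list(masses.values()),
                                   noisy_cohort.n / len(masses))
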