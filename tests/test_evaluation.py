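"""Closed-form metrics, stratified CV, repeated simulations, bootstrap."""

import numpy as np
import pytest

from headachedx import (
    PipelineConfig,
    PredictionSet,
    accuracy,
    bootstrap_compare,
    cohen_kappa,
    run_simulations,
    sensitivity_specificity,
    stratified_kfold_predict,
)


def ps(y, y_hat, classes=None):
    classes = classes or sorted(set(y) | set(y_hat))
    return PredictionSet(list(y), list(y_hat), classes)


class TestClosedForms:
    def test_accuracy_examples(self):
        assert accuracy(ps("mtc", "mtc")) == 1.0
        assert accuracy(ps("mmtc", "mttc")) == 0.75

    def test_accuracy_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(0)
        y = rng.choice(list("abc"), size=50)
        y_hat = rng.choice(list("abc"), size=50)
        base = accuracy(ps(y, y_hat, list("abc")))
        perm = rng.permutation(50)
        assert accuracy(ps(y[perm], y_hat[perm], list("abc"))) == base

    def test_kappa_zero_when_agreement_matches_chance(self):
        # p_o = 0.5 and p_e = 0.5 exactly
        assert cohen_kappa(ps("aabb", "aaaa")) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_worked_example_two_thirds_agreement(self):
        # p_o = 2/3, p_e = 4/9 -> kappa = 0.4
        assert cohen_kappa(ps("abb", "aab")) == pytest.approx(0.4, abs=1e-12)

    def test_perfect_agreement_gives_kappa_one(self):
        assert cohen_kappa(ps("abcabc", "abcabc")) == pytest.approx(1.0)

    def test_degenerate_expected_agreement_warns_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert cohen_kappa(ps("aa", "aa", ["a"])) == 0.0
        assert "p_e = 1" in caplog.text

    def test_sensitivity_specificity_from_two_by_two_table(self):
        sens, spec = sensitivity_specificity(ps("ccmm", "cmmm"), "c")
        assert (sens, spec) == (0.5, 1.0)
        for c in "cm":
            assert sensitivity_specificity(ps("ccmm", "ccmm"), c) == (1.0, 1.0)

    def test_absent_never_predicted_class_degenerates(self, caplog):
        p = ps("mmm", "mmm", classes=["m", "c"])
        with caplog.at_level("WARNING"):
            sens, spec = sensitivity_specificity(p, "c")
        assert (sens, spec) == (0.0, 1.0)
        assert "absent" in caplog.text

    def test_micro_averaged_sensitivity_equals_accuracy_for_two_classes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.choice(["a", "b"], size=n)
            y_hat = rng.choice(["a", "b"], size=n)
            p = ps(y, y_hat, ["a", "b"])
            tp = sum(
                sensitivity_specificity(p, c)[0] * np.sum(y == c) for c in "ab"
            )
            assert tp / n == pytest.approx(accuracy(p), abs=1e-12)


class TestStratifiedCV:
    def test_out_of_fold_predictions_cover_every_sample_once(self, noisy_cohort):
        small = noisy_cohort.subset(range(200))
        p = stratified_kfold_predict(small, 5, seed=3)
        assert len(p.y_hat) == small.n
        assert set(p.y_hat) <= set(small.classes)

    def test_fold_assignment_and_predictions_deterministic(self, kb, noisy_cohort):
        small = noisy_cohort.subset(range(200))
        config = PipelineConfig(balance="pk", kb=kb)
        p1 = stratified_kfold_predict(small, 5, config, seed=11)
        p2 = stratified_kfold_predict(small, 5, config, seed=11)
        assert p1.y_hat == p2.y_hat

    def test_folds_reduced_when_a_class_is_tiny(self, kb, noisy_cohort, caplog):
        idx = [i for i, l in enumerate(noisy_cohort.labels) if l != "cluster"][:60]
        idx += [i for i, l in enumerate(noisy_cohort.labels) if l == "cluster"][:3]
        small = noisy_cohort.subset(idx)
        with caplog.at_level("WARNING"):
            p = stratified_kfold_predict(small, 5, seed=0)
        assert "reducing folds" in caplog.text
        assert len(p.y_hat) == small.n

    def test_wf_and_rbf_feature_modes_run_leakage_free(self, kb, noisy_cohort):
        small = noisy_cohort.subset(range(120))
        for metric, mode in (("wf", "only"), ("rbf", "augment")):
            config = PipelineConfig(kb=kb, features=metric, feature_mode=mode)
            p = stratified_kfold_predict(small, 3, config, seed=2)
            assert accuracy(p) > 0.7


class TestSimulations:
    def test_single_simulation_has_zero_sds(self, kb, noisy_cohort):
        small = noisy_cohort.subset(range(150))
        report = run_simulations(small, ["none"], 1, seed=5,
                                 base_config=PipelineConfig(kb=kb))
        for metric in report.metrics:
            assert report.sd("none", metric) == 0.0

    def test_report_layout_covers_all_techniques_and_metrics(self, kb,
                                                             noisy_cohort):
        small = noisy_cohort.subset(range(150))
        techniques = ["none", "weights", "smote", "adasyn", "pk"]
        report = run_simulations(small, techniques, 2, seed=5,
                                 base_config=PipelineConfig(kb=kb))
        frame = report.to_frame()
        assert frame.shape[0] == 5
        expected_metrics = {"accuracy", "kappa"} | {
            f"{kind}_{c}"
            for kind in ("sensitivity", "specificity")
            for c in small.classes
        }
        assert set(report.metrics) == expected_metrics
        table = report.to_table(n_boot=200, seed=0)
        assert list(table.index) == [
            "none", "weights", "smote", "adasyn", "prior-knowledge"
        ]
        assert all("±" in cell for cell in table.loc["none"])

    def test_identical_seeds_give_identical_reports(self, kb, noisy_cohort):
        small = noisy_cohort.subset(range(150))
        reports = [
            run_simulations(small, ["none", "weights"], 2, seed=9,
                            base_config=PipelineConfig(kb=kb))
            for _ in range(2)
        ]
        for tech in reports[0].techniques:
            for metric in reports[0].metrics:
                np.testing.assert_array_equal(
                    reports[0].samples[tech][metric],
                    reports[1].samples[tech][metric],
                )

    def test_unknown_technique_rejected(self, noisy_cohort):
        with pytest.raises(ValueError, match="unknown balancing tag"):
            run_simulations(noisy_cohort, ["undersample"], 1)


class TestBootstrap:
    def test_identical_samples_are_not_significant(self):
        a = np.linspace(0.8, 0.95, 30)
        res = bootstrap_compare(a, a.copy(), n_boot=2000, seed=0)
        assert res.observed_difference == 0.0
        assert res.p_value >= 0.9
        assert not res.significant

    def test_constant_shift_is_highly_significant(self):
        a = np.full(100, 0.9)
        b = np.full(100, 0.7)
        res = bootstrap_compare(a, b, n_boot=2000, seed=0)
        assert res.observed_difference == pytest.approx(0.2)
        assert res.p_value < 0.01

    def test_p_value_symmetric_under_swap(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.9, 0.02, size=40)
        b = rng.normal(0.88, 0.02, size=40)
        p_ab = bootstrap_compare(a, b, n_boot=3000, seed=4).p_value
        p_ba = bootstrap_compare(b, a, n_boot=3000, seed=4).p_value
        assert p_ab == p_ba

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            bootstrap_compare([1, 2, 3], [1, 2])
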