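import numpy as np
import pytest

from thyrisk.cohort import stratified_split
from thyrisk.scoring import (
    ClassifierSpec,
    MetricSet,
    benign_f1,
    classifier_metrics,
    ensemble_risk_scores,
    optimal_probability_cutoff,
    summarize_over_repetitions,
    train_and_score,
)
from thyrisk.synthetic import default_config, generate_cohort


@pytest.fixture(scope="module")
def cohort400():
    return generate_cohort(default_config(n=400, seed=40))


class TestTrainAndScore:
    def test_probabilities_cover_cohort_and_stay_bounded(self, cohort400):
        train = np.zeros(len(cohort400), dtype=bool)
        train[:200] = True
        probs = train_and_score(
            cohort400, train, ClassifierSpec(name="logistic"), features=["age"]
        )
        assert probs.shape == (len(cohort400),)
        assert np.all((0 <= probs) & (probs <= 1))

    def test_logistic_separable_toy(self):
        from thyrisk.cohort import CharacteristicSpec, Cohort, NoduleRecord

        schema = [CharacteristicSpec("size", "continuous")]
        records = [
            NoduleRecord(
                nodule_id=str(i),
                patient_id=str(i),
                sex="female",
                age=50,
                size=30.0 + i if i < 10 else 5.0 + i / 10,
                er=1,
                characteristics={},
                outcome="malignant" if i < 10 else "benign",
            )
            for i in range(20)
        ]
        cohort = Cohort(schema, records)
        probs = train_and_score(
            cohort,
            np.ones(20, dtype=bool),
            ClassifierSpec(name="logistic"),
            features=["size"],
        )
        assert (probs[:10] > 0.99).all() and (probs[10:] < 0.01).all()

    def test_pure_noise_feature_carries_no_signal(self):
        """Under a permutation-null feature the classifiers cannot rank the
        held-out nodules (AUC ~ 0.5), and the calibrated logistic
        probabilities average to the training prevalence.  Random-forest
        vote fractions are majority votes, not calibrated probabilities, so
        only the no-ranking property applies to them."""
        from thyrisk.diagnostics import rank_auc

        cfg = default_config(n=600, seed=41)
        cfg.prevalence = 0.5
        cfg.conditional_probs = {
            "noise": {
                "benign": {"a": 0.5, "b": 0.5},
                "malignant": {"a": 0.5, "b": 0.5},
            }
        }
        cohort = generate_cohort(cfg)
        train = np.arange(len(cohort)) < 300
        held = ~train
        y = cohort.outcomes()
        rf_probs = train_and_score(cohort, train, ClassifierSpec(), features=["noise"])
        assert abs(rank_auc(rf_probs[held], y[held]) - 0.5) < 0.1
        lr_probs = train_and_score(
            cohort, train, ClassifierSpec(name="logistic"), features=["noise"]
        )
        prevalence = y[train].mean()
        se = np.sqrt(prevalence * (1 - prevalence) / train.sum())
        assert abs(lr_probs[held].mean() - prevalence) < 3 * se
        assert abs(rank_auc(lr_probs[held], y[held]) - 0.5) < 0.1

    def test_deterministic_given_seed(self, cohort400):
        train = stratified_split(cohort400, seed=1) == "train"
        a = train_and_score(cohort400, train, ClassifierSpec(seed=3), ["component", "age"])
        b = train_and_score(cohort400, train, ClassifierSpec(seed=3), ["component", "age"])
        assert np.array_equal(a, b)

    def test_single_class_training_rejected(self, cohort400):
        y = cohort400.outcomes()
        train = y == 1
        with pytest.raises(ValueError):
            train_and_score(cohort400, train, ClassifierSpec(), ["component"])

    def test_unknown_backend_rejected(self, cohort400):
        with pytest.raises(KeyError):
            train_and_score(
                cohort400,
                np.ones(len(cohort400), dtype=bool),
                ClassifierSpec(name="quantum"),
            )


class TestEnsembleRiskScores:
    def test_r1_equals_single_repetition(self, cohort400):
        table = ensemble_risk_scores(
            cohort400, ClassifierSpec(), ["component", "age"], R=1, seed=8
        )
        assert np.array_equal(table.scores, table.probabilities[0])
        assert (table.n_contributing == 1).all()

    def test_scores_bounded_and_signal_recovered(self, cohort400):
        table = ensemble_risk_scores(
            cohort400, ClassifierSpec(), ["component", "age", "margin"], R=4, seed=9
        )
        assert np.all((0 <= table.scores) & (table.scores <= 1))
        y = table.y
        assert table.scores[y == 1].mean() > table.scores[y == 0].mean()

    def test_out_of_split_uses_only_held_out_repetitions(self, cohort400):
        table = ensemble_risk_scores(
            cohort400, ClassifierSpec(name="logistic"), ["component", "age"], R=25,
            seed=10, mode="out_of_split",
        )
        held = table.partitions != "train"
        assert np.array_equal(table.n_contributing, held.sum(axis=0))
        i = int(np.argmax(held.sum(axis=0)))
        manual = table.probabilities[held[:, i], i].mean()
        assert table.scores[i] == pytest.approx(manual)

    def test_deterministic_given_seed(self, cohort400):
        a = ensemble_risk_scores(cohort400, ClassifierSpec(), ["age"], R=2, seed=11)
        b = ensemble_risk_scores(cohort400, ClassifierSpec(), ["age"], R=2, seed=11)
        assert np.array_equal(a.scores, b.scores)

    def test_invalid_mode_rejected(self, cohort400):
        with pytest.raises(ValueError):
            ensemble_risk_scores(cohort400, ClassifierSpec(), None, R=2, seed=0, mode="oob")


class TestOptimalCutoff:
    def test_perfect_separation_gap_midpoint(self):
        scores = np.r_[np.linspace(0, 0.2, 5), np.linspace(0.8, 1.0, 5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        t = optimal_probability_cutoff(scores, labels)
        assert t == pytest.approx(0.5)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            t = optimal_probability_cutoff(scores, labels)
            uniq = np.unique(scores)
            cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
            best, best_d = None, np.inf
            for c in cands:
                pred = scores > c
                sen = np.sum(pred & (labels == 1)) / labels.sum()
                spe = np.sum(~pred & (labels == 0)) / (len(labels) - labels.sum())
                d = np.hypot(1 - sen, 1 - spe)
                if d < best_d - 1e-12:
                    best, best_d = c, d
            assert t == best

    def test_label_swap_symmetry(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = optimal_probability_cutoff(scores, labels)
        pred = scores > t
        sen = np.mean(pred[labels == 1])
        spe = np.mean(~pred[labels == 0])
        # swapping labels and negating scores swaps the roles of SEN and SPE
        t2 = optimal_probability_cutoff(-scores, 1 - labels)
        pred2 = -scores > t2
        assert np.mean(pred2[labels == 0]) == pytest.approx(spe)
        assert np.mean(~pred2[labels == 1]) == pytest.approx(sen)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_probability_cutoff([0.1, 0.9], [1, 1])


class TestClassifierMetrics:
    def test_benign_f1_identity_example(self):
        assert round(benign_f1(spe=0.880, npv=0.611), 3) == 0.721

    def test_perfect_classifier_all_ones(self):
        m = classifier_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert (m.auc, m.sen, m.f1, m.spe, m.ppv, m.npv) == (1, 1, 1, 1, 1, 1)

    def test_f1_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(10, 50))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            thr = float(rng.random())
            m = classifier_metrics(scores, labels, thr)
            pred_ben = scores <= thr
            is_ben = labels == 0
            tp_b = np.sum(pred_ben & is_ben)
            if m.f1 is None:
                assert pred_ben.sum() == 0 or m.npv is None
                continue
            prec = tp_b / pred_ben.sum() if pred_ben.sum() else np.nan
            rec = tp_b / is_ben.sum()
            expected = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            assert m.f1 == pytest.approx(expected)

    def test_auc_is_threshold_free(self):
        scores = np.array([0.2, 0.4, 0.5, 0.7, 0.9])
        labels = np.array([0, 1, 0, 1, 1])
        aucs = {classifier_metrics(scores, labels, t).auc for t in (0.1, 0.5, 0.85)}
        assert len(aucs) == 1

    def test_empty_predicted_class_reported_absent(self):
        m = classifier_metrics([0.6, 0.7, 0.8, 0.9], [0, 1, 0, 1], 0.5)
        assert m.npv is None and m.f1 is None


class TestSummarize:
    def _ms(self, auc, npv=0.5):
        return MetricSet(auc=auc, sen=0.9, f1=0.7, spe=0.8, ppv=0.95, npv=npv)

    def test_identical_repetitions_identity(self):
        s = summarize_over_repetitions([self._ms(0.9)] * 3)
        assert s.means["auc"] == 0.9 and s.counts["auc"] == 3

    def test_mean_of_two(self):
        s = summarize_over_repetitions([self._ms(0.9), self._ms(1.0)])
        assert s.means["auc"] == pytest.approx(0.95)

    def test_absent_values_ignored_with_count(self):
        s = summarize_over_repetitions([self._ms(0.9, npv=None), self._ms(0.9, npv=0.4)])
        assert s.counts["npv"] == 1 and s.means["npv"] == 0.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_over_repetitions([])
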