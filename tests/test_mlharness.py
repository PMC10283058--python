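"""Discovery/validation splitting, the seven-algorithm harness and the
evaluation-metric suite (brute-force checked)."""

import numpy as np
import pandas as pd
import pytest

import uromics as u
from uromics.mlharness import ALGORITHMS, combine_blocks, evaluate


class TestSplit:
    def test_exact_divisibility(self):
        ids = [f"s{i}" for i in range(18)]
        labels = ["HC"] * 9 + ["T2DM"] * 9
        plan = u.split_discovery_validation(ids, labels, seed=0)
        assert len(plan.discovery_ids) == 12 and len(plan.validation_ids) == 6
        for cls in ("HC", "T2DM"):
            n_d = sum(1 for i, l in zip(ids, labels)
                      if l == cls and i in set(plan.discovery_ids))
            assert n_d == 6

    def test_rounding_contract(self):
        ids = [f"s{i}" for i in range(20)]
        labels = ["A"] * 10 + ["B"] * 10
        plan = u.split_discovery_validation(ids, labels, seed=1)
        for cls in ("A", "B"):
            n_v = sum(1 for i, l in zip(ids, labels)
                      if l == cls and i in set(plan.validation_ids))
            assert abs(n_v - 10 / 3) <= 1

    def test_deterministic_and_partitioning(self):
        ids = [f"s{i}" for i in range(30)]
        labels = (["A"] * 12 + ["B"] * 18)
        p1 = u.split_discovery_validation(ids, labels, seed=7)
        p2 = u.split_discovery_validation(ids, labels, seed=7)
        assert p1.discovery_ids == p2.discovery_ids
        assert set(p1.discovery_ids) | set(p1.validation_ids) == set(ids)
        assert not set(p1.discovery_ids) & set(p1.validation_ids)

    def test_small_class_rejected_by_name(self):
        with pytest.raises(ValueError, match="B"):
            u.split_discovery_validation(["a", "b", "c", "d"],
                                         ["A", "A", "A", "B"])


def brute_metrics(tn, fp, fn, tp):
    n = tn + fp + fn + tp
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n ** 2
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn)
    return {
        "accuracy": po,
        "kappa": (po - pe) / (1 - pe) if pe != 1 else 0.0,
        "precision": prec,
        "recall": rec,
        "specificity": tn / (tn + fp),
        "f": 2 * prec * rec / (prec + rec) if prec + rec else 0.0,
    }


def brute_auc(scores, truth):
    """Mann-Whitney with ties counted 1/2."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluate:
    def test_confusion_worked_example(self):
        # [[45, 5], [10, 40]]: accuracy 0.85, kappa 0.70
        truth = np.array([0] * 50 + [1] * 50)
        pred = np.array([0] * 45 + [1] * 5 + [0] * 10 + [1] * 40)
        rep = evaluate(truth, predicted=pred, positive=1)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_precision_f_measure_worked_example(self):
        # TP=40, FP=10, FN=5 -> precision 0.800, F = 0.842
        truth = np.array([1] * 45 + [0] * 20)
        pred = np.concatenate([np.ones(40), np.zeros(5),
                               np.ones(10), np.zeros(10)])
        rep = evaluate(truth, predicted=pred, positive=1)
        assert rep.precision == pytest.approx(0.800)
        assert rep.f_measure == pytest.approx(2 * 0.8 * (40 / 45)
                                              / (0.8 + 40 / 45), abs=5e-4)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1, 1])
        rep = evaluate(truth, predicted=truth, scores=truth.astype(float),
                       positive=1)
        assert rep.auc == 1.0 and rep.accuracy == 1.0 and rep.kappa == 1.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 40))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            pred = rng.integers(0, 2, n)
            scores = np.round(rng.uniform(0, 1, n), 2)   # force some ties
            rep = evaluate(truth, predicted=pred, scores=scores, positive=1)
            tn, fp, fn, tp = rep.confusion.ravel()
            bm = brute_metrics(tn, fp, fn, tp)
            assert rep.accuracy == pytest.approx(bm["accuracy"])
            assert rep.kappa == pytest.approx(bm["kappa"])
            assert rep.precision == pytest.approx(bm["precision"])
            assert rep.f_measure == pytest.approx(bm["f"])
            assert rep.specificity == pytest.approx(bm["specificity"])
            assert rep.auc == pytest.approx(brute_auc(scores, truth == 1))

    def test_auc_invariant_under_monotone_transform(self, rng):
        truth = rng.integers(0, 2, 60)
        truth[:5] = 0; truth[-5:] = 1
        scores = rng.uniform(0, 1, 60)
        a = evaluate(truth, scores=scores, positive=1).auc
        b = evaluate(truth, scores=np.exp(5 * scores), positive=1).auc
        assert a == pytest.approx(b)

    def test_single_class_auc_flagged(self):
        rep = evaluate(np.ones(5), scores=np.linspace(0, 1, 5), positive=1)
        assert np.isnan(rep.auc)
        assert any("AUC" in n for n in rep.notes)


class TestTrainPairwise:
    def test_separable_data_all_algorithms(self, two_group_cohort):
        co = two_group_cohort
        X = np.log2(u.average_replicates(co.intensities))
        labels = co.sample_metadata()["group"].reindex(X.index)
        plan = u.split_discovery_validation(X.index.to_numpy(),
                                            labels.to_numpy(), seed=0)
        y_d = labels.loc[plan.discovery_ids].to_numpy()
        y_v = labels.loc[plan.validation_ids].to_numpy()
        for alg in ALGORITHMS:
            scorer = u.train_pairwise(alg, X.loc[plan.discovery_ids], y_d,
                                      seed=0)
            acc = np.mean(scorer.predict(X.loc[plan.validation_ids]) == y_v)
            assert acc >= 0.85, alg
            s = scorer.score_samples(X.loc[plan.validation_ids])
            assert np.all((s >= 0) & (s <= 1))

    def test_shuffled_labels_near_chance(self, two_group_cohort, rng):
        co = two_group_cohort
        X = np.log2(u.average_replicates(co.intensities))
        labels = co.sample_metadata()["group"].reindex(X.index).to_numpy()
        accs = []
        for s in range(5):
            perm = rng.permutation(len(labels))
            y = labels[perm]
            plan = u.split_discovery_validation(X.index.to_numpy(), y, seed=s)
            pos = {i: l for i, l in zip(X.index, y)}
            y_d = np.array([pos[i] for i in plan.discovery_ids])
            y_v = np.array([pos[i] for i in plan.validation_ids])
            scorer = u.train_pairwise("Logi", X.loc[plan.discovery_ids], y_d,
                                      seed=s)
            accs.append(np.mean(scorer.predict(X.loc[plan.validation_ids]) == y_v))
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_constant_features_fall_back_to_majority(self):
        X = np.ones((20, 3))
        y = np.array(["A"] * 8 + ["B"] * 12)
        scorer = u.train_pairwise("SVM", X, y, seed=0)
        assert scorer.majority_fallback == "B"
        assert np.all(scorer.predict(np.ones((4, 3))) == "B")

    def test_validation_rows_cannot_leak_into_cv(self, rng):
        """Leakage canary: a feature that encodes the label only on
        validation rows must not raise discovery CV accuracy."""
        n = 60
        X = rng.normal(0, 1, (n, 10))
        y = np.array(["A", "B"] * (n // 2))
        ids = np.arange(n)
        plan = u.split_discovery_validation(ids, y, seed=0)
        canary = rng.normal(0, 1, n)
        canary[plan.validation_ids] = (y[plan.validation_ids] == "B") * 10.0
        Xc = np.column_stack([X, canary])
        scorer = u.train_pairwise("Logi", Xc[plan.discovery_ids],
                                  y[plan.discovery_ids], seed=0)
        assert scorer.cv_accuracy < 0.7


class TestMultiomicsComparison:
    def test_identical_modalities_no_gain(self, two_group_cohort):
        co = two_group_cohort
        X = np.log2(u.average_replicates(co.intensities))
        met = X[co.modality_columns("metabolite")]
        labels = co.sample_metadata()["group"].reindex(X.index)
        pep = met.copy()
        pep.columns = [c.replace("met", "pep") for c in met.columns]
        tab = u.compare_single_vs_multiomics(met, pep, labels,
                                             algorithms=("Logi", "LDA"),
                                             seed=0)
        m = tab[tab.algorithm == "MEAN"].set_index("source")["accuracy"]
        assert abs(m["combined"] - m["met"]) < 0.12

    def test_id_mismatch_rejected(self, two_group_cohort):
        co = two_group_cohort
        X = np.log2(u.average_replicates(co.intensities))
        met = X[co.modality_columns("metabolite")]
        pep = X[co.modality_columns("peptide")].iloc[::-1]
        labels = co.sample_metadata()["group"]
        with pytest.raises(ValueError, match="mismatch"):
            u.compare_single_vs_multiomics(met, pep, labels)

    def test_combine_blocks_balances_scale(self, rng):
        met = pd.DataFrame(rng.normal(0, 1, (20, 3)))
        pep = pd.DataFrame(rng.normal(0, 1000, (20, 4)),
                           columns=["a", "b", "c", "d"])
        both = combine_blocks(met, pep)
        sds = both.std(axis=0, ddof=1)
        assert sds.max() / sds.min() < 1.01
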