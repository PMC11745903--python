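"""Split strategies, metric oracles, and cross-validation bookkeeping."""

import numpy as np
import pytest

from hypersyn.data_io import DataError, SynergySample
from hypersyn.evaluation import (STRATEGIES, compute_metrics, make_splits,
                                 run_cv)


def toy_samples(n_drugs=12, n_cells=8, n=500, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    cells = [f"c{i}" for i in range(n_cells)]
    out = []
    for _ in range(n):
        a, b = rng.choice(n_drugs, size=2, replace=False)
        out.append(SynergySample(drugs[a], drugs[b],
                                 cells[int(rng.integers(n_cells))],
                                 float(rng.normal(25, 15))).with_label())
    return out


def drugs_of(sample):
    return {sample.drug_a, sample.drug_b}


class TestMakeSplits:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_fold_and_test_disjointness(self, strategy):
        samples = toy_samples()
        plan = make_splits(samples, strategy, k=5, seed=3)
        test = set(plan.test_indices)
        for fold in plan.folds:
            tr, va = set(fold.train_indices), set(fold.val_indices)
            assert not tr & va
            assert not (tr | va) & test

    @pytest.mark.parametrize("strategy", ["random", "cline", "drugcomb"])
    def test_each_pool_sample_validated_exactly_once(self, strategy):
        samples = toy_samples()
        plan = make_splits(samples, strategy, k=5, seed=3)
        pool = set(range(len(samples))) - set(plan.test_indices)
        seen = []
        for fold in plan.folds:
            seen.extend(fold.val_indices)
            assert set(fold.train_indices) | set(fold.val_indices) == pool
        assert sorted(seen) == sorted(pool)

    def test_cline_validation_cell_lines_unseen_in_training(self):
        samples = toy_samples()
        plan = make_splits(samples, "cline", k=5, seed=1)
        for fold in plan.folds:
            val_cells = {samples[i].cell_line for i in fold.val_indices}
            train_cells = {samples[i].cell_line for i in fold.train_indices}
            assert not val_cells & train_cells

    def test_cline_even_partition_without_test_split(self):
        samples = toy_samples(n_cells=10)
        plan = make_splits(samples, "cline", k=5, test_fraction=0.0, seed=1)
        for fold in plan.folds:
            val_cells = {samples[i].cell_line for i in fold.val_indices}
            assert len(val_cells) == 2

    def test_drugcomb_pairs_disjoint_between_train_and_val(self):
        samples = toy_samples()
        plan = make_splits(samples, "drugcomb", k=5, seed=2)
        for fold in plan.folds:
            val_pairs = {frozenset(drugs_of(samples[i]))
                         for i in fold.val_indices}
            train_pairs = {frozenset(drugs_of(samples[i]))
                           for i in fold.train_indices}
            assert not val_pairs & train_pairs

    def test_drugsingle_exactly_one_novel_drug(self):
        samples = toy_samples()
        plan = make_splits(samples, "drugsingle", k=5, seed=4)
        for fold in plan.folds:
            train_drugs = set().union(*(drugs_of(samples[i])
                                        for i in fold.train_indices))
            for i in fold.val_indices:
                novel = drugs_of(samples[i]) - train_drugs
                assert len(novel) == 1

    def test_drugdouble_both_drugs_novel(self):
        samples = toy_samples()
        plan = make_splits(samples, "drugdouble", k=5, seed=4)
        for fold in plan.folds:
            train_drugs = set().union(*(drugs_of(samples[i])
                                        for i in fold.train_indices))
            for i in fold.val_indices:
                assert not drugs_of(samples[i]) & train_drugs

    def test_drugsingle_and_drugdouble_val_sets_disjoint(self):
        samples = toy_samples()
        single = make_splits(samples, "drugsingle", k=5, seed=4)
        double = make_splits(samples, "drugdouble", k=5, seed=4)
        for fs, fd in zip(single.folds, double.folds):
            assert not set(fs.val_indices) & set(fd.val_indices)

    def test_drugdouble_two_group_toy_case(self):
        samples = [SynergySample("A", "B", "c1", 40.0).with_label(),
                   SynergySample("C", "D", "c1", 10.0).with_label()]
        plan = make_splits(samples, "drugdouble", k=2, test_fraction=0.0,
                           seed=0)
        for fold in plan.folds:
            assert len(fold.train_indices) == 1
            assert len(fold.val_indices) == 1
            assert fold.train_indices != fold.val_indices

    def test_membership_stable_under_sample_reordering(self):
        samples = toy_samples()
        plan1 = make_splits(samples, "cline", k=5, seed=9)
        perm = np.random.default_rng(0).permutation(len(samples))
        reordered = [samples[i] for i in perm]
        plan2 = make_splits(reordered, "cline", k=5, seed=9)
        val_cells_1 = [{samples[i].cell_line for i in f.val_indices}
                       for f in plan1.folds]
        val_cells_2 = [{reordered[i].cell_line for i in f.val_indices}
                       for f in plan2.folds]
        assert val_cells_1 == val_cells_2

    def test_too_few_units_is_an_error(self):
        samples = toy_samples(n_cells=3)
        with pytest.raises(DataError, match="3"):
            make_splits(samples, "cline", k=5, test_fraction=0.0, seed=0)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            make_splits(toy_samples(n=10), "bogus")


def auroc_pair_counting(labels, scores):
    """Wilcoxon-Mann-Whitney oracle: fraction of correctly ordered
    positive-negative pairs, ties counted half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (m.auroc, m.auprc, m.f1) == (1.0, 1.0, 1.0)

    def test_printed_toy_case(self):
        m = compute_metrics([0, 1, 0, 1], [0.1, 0.2, 0.3, 0.4])
        assert m.auroc == pytest.approx(0.75, abs=1e-12)

    def test_all_tied_scores_give_half(self):
        m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m.auroc == pytest.approx(0.5, abs=1e-12)

    def test_matches_pair_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # induce some ties
            got = compute_metrics(labels, scores).auroc
            want = auroc_pair_counting(labels, scores)
            assert abs(got - want) < 1e-12

    def test_single_class_is_an_error(self):
        with pytest.raises(DataError):
            compute_metrics([1, 1, 1], [0.1, 0.2, 0.3])

    def test_f1_threshold_configurable(self):
        m = compute_metrics([1, 0], [0.6, 0.4], f1_threshold=0.7)
        assert m.f1 == 0.0  # nothing predicted positive at 0.7


class TestRunCv:
    def test_bookkeeping_and_determinism(self, small_synth_cohort):
        from hypersyn.synergy_model import TrainConfig
        _, cohort = small_synth_cohort
        tc = TrainConfig(common_dim=8, gtn_layers=1, refinement_layers=1,
                         predictor_hidden=(16,), max_epochs=3, patience=3,
                         batch_size=128, seed=5)
        res1 = run_cv(cohort, "random", tc, k=2, test_fraction=0.1)
        res2 = run_cv(cohort, "random", tc, k=2, test_fraction=0.1)
        assert len(res1.fold_metrics) == 2
        assert res1.mean.auroc == pytest.approx(
            np.mean([m.auroc for m in res1.fold_metrics]))
        assert [m.auroc for m in res1.fold_metrics] == \
            [m.auroc for m in res2.fold_metrics]
        assert res1.test_metrics.auroc == res2.test_metrics.auroc
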