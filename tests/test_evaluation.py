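import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from mcbfsnw import ExpressionDataset
from mcbfsnw.evaluation import (
    KNNClassifier,
    best_prefix,
    compute_metrics,
    exhaustive_search,
    filter_key_genes,
    knn_predict,
    make_classifier,
    repeated_cv,
    ttest_genes,
)
from mcbfsnw.data_io import GeneRanking
from mcbfsnw.synthetic import ExpressionScenario, simulate_expression


def _dataset(values, labels, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids or [f"g{k}" for k in range(values.shape[1])],
        labels=labels,
    )


class TestKNN:
    def test_k1_recovers_training_point(self):
        X = np.array([[0.0], [1.0], [2.0]])
        clf = KNNClassifier(k=1).fit(X, ["a", "b", "a"])
        assert clf.predict(np.array([[1.0]])) == ["b"]

    def test_k_equals_n_gives_majority(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        clf = KNNClassifier(k=4).fit(X, ["a", "a", "a", "b"])
        assert clf.predict(np.array([[9.9], [-5.0]])) == ["a", "a"]

    def test_hand_sorted_toy_set(self):
        # six labeled 2-D points; expectations from sorting distances by hand
        X = np.array([[0, 0], [1, 0], [0, 1], [4, 4], [5, 4], [4, 5]],
                     dtype=float)
        y = ["blue", "blue", "blue", "red", "red", "red"]
        clf = KNNClassifier(k=3).fit(X, y)
        assert clf.predict(np.array([[0.2, 0.2], [4.5, 4.5], [2.0, 2.0]])) == \
            ["blue", "red", "blue"]  # (2,2): nearest are (1,0),(0,1),(0,0)

    def test_distance_tie_prefers_lower_training_index(self):
        X = np.array([[1.0], [-1.0], [2.0]])
        clf = KNNClassifier(k=1).fit(X, ["a", "b", "c"])
        # test point 0 is equidistant from index 0 and 1; index 0 wins
        assert clf.predict(np.array([[0.0]])) == ["a"]

    def test_vote_tie_broken_by_nearest(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        clf = KNNClassifier(k=4).fit(X, ["a", "a", "b", "b"])
        assert clf.predict(np.array([[0.5]])) == ["a"]
        assert clf.predict(np.array([[10.5]])) == ["b"]

    def test_empty_gene_subset_is_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="empty gene subset"):
            knn_predict(tiny_dataset, [], tiny_dataset.values, k=1)

    def test_knn_predict_restricts_genes(self, tiny_dataset):
        pred = knn_predict(tiny_dataset, ["g1"],
                           tiny_dataset.values[:, :1], k=1)
        assert pred == tiny_dataset.labels


class TestMetrics:
    def test_perfect_prediction(self):
        y = ["a", "b", "a", "b"]
        ms = compute_metrics(y, y)
        assert (ms.acc, ms.sn, ms.sp, ms.f_score, ms.mcc, ms.kappa) == \
            (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_example(self):
        # TP=3, TN=4, FP=1, FN=2 with positive label "pos"
        y_true = ["pos"] * 5 + ["neg"] * 5
        y_pred = ["pos"] * 3 + ["neg"] * 2 + ["pos"] * 1 + ["neg"] * 4
        ms = compute_metrics(y_true, y_pred, positive_label="pos")
        assert ms.acc == pytest.approx(0.7)
        assert ms.sn == pytest.approx(0.6)
        assert ms.sp == pytest.approx(0.8)
        assert ms.f_score == pytest.approx(0.66667, abs=1e-5)
        assert ms.mcc == pytest.approx(0.40825, abs=1e-5)

    def test_constant_prediction_on_balanced_truth_has_zero_kappa(self):
        y_true = ["a", "a", "b", "b"]
        y_pred = ["a", "a", "a", "a"]
        ms = compute_metrics(y_true, y_pred)
        assert ms.kappa == 0.0

    def test_default_positive_is_lexicographically_larger(self):
        ms = compute_metrics(["a", "b"], ["a", "b"])
        assert ms.positive_label == "b"

    def test_label_swap_swaps_sn_sp(self):
        rng = np.random.default_rng(0)
        y_true = list(rng.choice(["x", "y"], 40))
        y_pred = list(rng.choice(["x", "y"], 40))
        m1 = compute_metrics(y_true, y_pred, positive_label="x")
        m2 = compute_metrics(y_true, y_pred, positive_label="y")
        assert m1.sn == pytest.approx(m2.sp)
        assert m1.sp == pytest.approx(m2.sn)
        assert m1.acc == pytest.approx(m2.acc)
        assert abs(m1.mcc) == pytest.approx(abs(m2.mcc))

    def test_multiclass_has_no_binary_fields(self):
        ms = compute_metrics(["a", "b", "c"], ["a", "b", "c"])
        assert ms.sn is None and ms.mcc is None
        assert ms.acc == 1.0 and ms.kappa == 1.0

    def test_kappa_matches_reference_implementation(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            c = int(rng.integers(2, 5))
            labels = [f"c{i}" for i in range(c)]
            y_true = list(rng.choice(labels, n))
            y_pred = list(rng.choice(labels, n))
            if len(set(y_true)) < 2:
                continue
            ms = compute_metrics(y_true, y_pred)
            ref = cohen_kappa_score(y_true, y_pred)
            if math.isnan(ref):
                continue
            assert ms.kappa == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(["n", "p"]), min_size=4, max_size=60),
           st.lists(st.sampled_from(["n", "p"]), min_size=4, max_size=60))
    def test_metric_bounds(self, y_true, y_pred):
        n = min(len(y_true), len(y_pred))
        y_true, y_pred = y_true[:n], y_pred[:n]
        if len(set(y_true)) < 2:
            y_true[0], y_true[1] = "n", "p"
        ms = compute_metrics(y_true, y_pred)
        assert 0 <= ms.acc <= 1
        assert 0 <= ms.sn <= 1 and 0 <= ms.sp <= 1 and 0 <= ms.f_score <= 1
        assert -1 <= ms.mcc <= 1 and -1 <= ms.kappa <= 1
        assert ms.confusion.sum() == n

    def test_unknown_positive_label(self):
        with pytest.raises(ValueError):
            compute_metrics(["a", "b"], ["a", "b"], positive_label="zzz")


class TestRepeatedCV:
    def test_fold_partition_property(self):
        data, _ = simulate_expression(ExpressionScenario(
            n_samples=40, n_genes=10, n_informative=2, seed=3))
        rep = repeated_cv(data, data.gene_ids[:3], folds=5, repeats=2, seed=1)
        total = sum(ms.confusion.sum() for ms in rep.per_fold)
        assert total == data.n_samples * 2  # each repeat partitions all samples
        assert len(rep.per_fold) == 5 * 2

    def test_identical_seed_is_deterministic(self, tiny_dataset):
        r1 = repeated_cv(tiny_dataset, ["g1", "g2"], folds=3, repeats=2,
                         seed=7, k=1)
        r2 = repeated_cv(tiny_dataset, ["g1", "g2"], folds=3, repeats=2,
                         seed=7, k=1)
        assert r1.means == r2.means and r1.sds == r2.sds

    def test_majority_classifier_hits_class_prior(self):
        # 70/30 binary data: always-majority scores ~0.7 accuracy
        rng = np.random.default_rng(5)
        values = rng.normal(size=(100, 4))
        labels = ["big"] * 70 + ["small"] * 30
        data = _dataset(values, labels)
        rep = repeated_cv(data, data.gene_ids, classifier="majority",
                          folds=10, repeats=2, seed=0)
        assert rep.means["acc"] == pytest.approx(0.7, abs=0.02)

    def test_folds_reduced_for_small_classes(self, tiny_dataset):
        rep = repeated_cv(tiny_dataset, ["g1"], folds=10, repeats=1, seed=0,
                          k=1)
        assert rep.folds == 3  # smallest class has 3 samples

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            _dataset(np.ones((4, 2)), ["a"] * 4)


class TestBestPrefix:
    def test_max_k_one(self, tiny_dataset):
        k, rep = best_prefix(tiny_dataset,
                             GeneRanking(["g1", "g2"], [2.0, 1.0]),
                             max_k=1, folds=3, repeats=1, seed=0, k=1)
        assert k == 1 and rep.gene_subset == ["g1"]

    def test_informative_first_gene_wins_small_prefix(self):
        data, truth = simulate_expression(ExpressionScenario(
            n_samples=40, n_genes=30, n_informative=1, effect_size=4, seed=9))
        informative = truth[0]
        others = [g for g in data.gene_ids if g != informative]
        ranking = GeneRanking([informative] + others,
                              list(range(30, 0, -1)))
        k, _ = best_prefix(data, ranking, max_k=5, folds=5, repeats=2, seed=0)
        assert k <= 3

    def test_tie_prefers_smaller_prefix(self):
        # perfectly separable on gene 1 alone: every prefix scores acc 1.0
        values = np.array([[0.0, 1.0], [0.1, 2.0], [5.0, 1.5], [5.1, 0.5]])
        data = _dataset(values, ["a", "a", "b", "b"])
        k, rep = best_prefix(data, GeneRanking(["g0", "g1"], [2.0, 1.0]),
                             max_k=2, folds=2, repeats=1, seed=0, k=1)
        assert rep.means["acc"] == 1.0 and k == 1


class TestExhaustiveSearch:
    def _split(self, seed=13, n_genes=10):
        data, truth = simulate_expression(ExpressionScenario(
            n_samples=60, n_genes=n_genes, n_informative=2, effect_size=3,
            seed=seed))
        train = _dataset(data.values[::2], [data.labels[i] for i in
                                            range(0, 60, 2)], data.gene_ids)
        test = _dataset(data.values[1::2], [data.labels[i] for i in
                                            range(1, 60, 2)], data.gene_ids)
        return train, test, truth

    def test_counts_all_nonempty_subsets(self):
        train, test, _ = self._split()
        res = exhaustive_search(train, test, train.gene_ids[:10], k=3)
        assert res.evaluated == 1023
        assert len(res.table) == 1023

    def test_matches_independent_reevaluation(self):
        train, test, _ = self._split(n_genes=6)
        cands = train.gene_ids[:5]
        res = exhaustive_search(train, test, cands, k=3)
        # independent loop: re-evaluate every subset from scratch
        best = None
        for size in range(1, len(cands) + 1):
            for combo in itertools.combinations(cands, size):
                pred = knn_predict(train.subset_genes(combo).subset_genes(combo),
                                   combo, test.subset_genes(combo).values, k=3)
                acc = float(np.mean([p == t for p, t in
                                     zip(pred, test.labels)]))
                key = (-acc, size, tuple(sorted(combo)))
                if best is None or key < best:
                    best = key
                    best_subset = list(combo)
        assert res.best_subset == best_subset
        assert res.best_metrics.acc == pytest.approx(-best[0])

    def test_jointly_informative_pair_found(self):
        hits = 0
        for seed in range(10):
            train, test, truth = self._split(seed=100 + seed, n_genes=8)
            res = exhaustive_search(train, test, train.gene_ids, k=5)
            hits += set(truth) <= set(res.best_subset) or \
                res.best_metrics.acc == 1.0 and len(
                    set(truth) & set(res.best_subset)) >= 1
        assert hits >= 9

    def test_single_candidate(self):
        train, test, _ = self._split(n_genes=3)
        res = exhaustive_search(train, test, [train.gene_ids[0]], k=3)
        assert res.evaluated == 1
        assert res.best_subset == [train.gene_ids[0]]

    def test_too_many_candidates_rejected(self):
        train, test, _ = self._split(n_genes=16)
        with pytest.raises(ValueError, match="prefix"):
            exhaustive_search(train, test, train.gene_ids)


class TestTTest:
    def test_equal_groups_give_t_zero(self):
        values = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        data = _dataset(values, ["a"] * 3 + ["b"] * 3)
        res = ttest_genes(data)
        assert res.loc["g0", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["g0", "p"] == pytest.approx(1.0)
        assert not res.loc["g0", "significant"]

    def test_separated_groups_significant(self):
        values = np.array([[0.0], [0.0], [1.0], [1.0],
                           [10.0], [10.0], [11.0], [11.0]])
        data = _dataset(values, ["a"] * 4 + ["b"] * 4)
        res = ttest_genes(data)
        assert abs(res.loc["g0", "t"]) > 10
        assert res.loc["g0", "p"] < 0.05 and res.loc["g0", "significant"]

    def test_matches_welch_formula_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            na, nb = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.normal(), size=nb)
            values = np.concatenate([a, b])[:, None]
            data = _dataset(values, ["a"] * na + ["b"] * nb)
            t = float(ttest_genes(data).loc["g0", "t"])
            # Welch statistic written out by hand
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            want = (a.mean() - b.mean()) / math.sqrt(va + vb)
            assert t == pytest.approx(want, abs=1e-10)

    def test_degenerate_gene_flagged(self):
        values = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0], [5.0, 9.0]])
        data = _dataset(values, ["a", "a", "b", "b"])
        res = ttest_genes(data)
        assert np.isnan(res.loc["g0", "t"])
        assert not res.loc["g0", "significant"]


class TestKeyGeneFilter:
    # per-gene survival p-values supplied by an external analysis
    HUB_PVALUES = {
        "TEK": 8.90e-10, "ANGPT1": 4.30e-05, "CAV1": 4.90e-05,
        "SPP1": 0.0015, "CDH5": 0.0034, "PECAM1": 0.0036, "CLDN5": 0.045,
        "AGTR1": 0.054, "GJA4": 0.13, "FABP4": 0.25,
    }

    def test_seven_of_ten_hubs_pass_the_cutoff(self):
        kept = filter_key_genes(list(self.HUB_PVALUES), self.HUB_PVALUES)
        assert len(kept) == 7
        assert kept == ["TEK", "ANGPT1", "CAV1", "SPP1", "CDH5", "PECAM1",
                        "CLDN5"]

    def test_all_p_one_empty(self):
        assert filter_key_genes(["a", "b"], {"a": 1.0, "b": 1.0}) == []

    def test_all_p_zero_keeps_input_order(self):
        hubs = ["z", "a", "m"]
        assert filter_key_genes(hubs, {g: 0.0 for g in hubs}) == hubs

    def test_missing_pvalue_is_error(self):
        with pytest.raises(KeyError, match="b"):
            filter_key_genes(["a", "b"], {"a": 0.01})


class TestClassifierContract:
    def test_svm_rbf_behind_fit_predict(self, tiny_dataset):
        clf = make_classifier("svm-rbf")
        clf.fit(tiny_dataset.values, tiny_dataset.labels)
        pred = clf.predict(tiny_dataset.values)
        assert set(pred) <= set(tiny_dataset.labels)

    def test_deterministic_report_for_fixed_seed(self, tiny_dataset):
        r1 = repeated_cv(tiny_dataset, ["g1"], classifier="svm-rbf",
                         folds=3, repeats=2, seed=4)
        r2 = repeated_cv(tiny_dataset, ["g1"], classifier="svm-rbf",
                         folds=3, repeats=2, seed=4)
        assert r1.means == r2.means

    def test_unknown_descriptor(self):
        with pytest.raises(ValueError):
            make_classifier("random-forest")
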