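"""Metric formulas, Friedman rank test vs brute-force oracle, rank laws."""

import numpy as np
import pytest
from scipy import stats

import spliceconv as sc
from spliceconv.errors import EvaluationError
from spliceconv.evaluation import friedman_report, rank_table


# --------------------------------------------------------------------------
# independent oracles, written directly from the textbook definitions


def oracle_confusion(t, p):
    tp = sum(1 for a, b in zip(t, p) if a == 1 and b == 1)
    tn = sum(1 for a, b in zip(t, p) if a == 0 and b == 0)
    fp = sum(1 for a, b in zip(t, p) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(t, p) if a == 1 and b == 0)
    return tp, tn, fp, fn


def oracle_metrics(tp, tn, fp, fn):
    recall = tp / (tp + fn) if tp + fn else None
    precision = tp / (tp + fp) if tp + fp else None
    accuracy = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return recall, precision, accuracy, f1


def oracle_friedman(acc):
    """Brute-force Friedman statistic: explicit per-test tie-averaged ranks,
    rank-sum formula, explicit tie correction."""
    m, k = acc.shape
    ranks = np.empty((m, k))
    for j in range(k):
        col = acc[:, j]
        order = sorted(range(m), key=lambda i: -col[i])
        r = np.empty(m)
        i = 0
        while i < m:
            tied = [order[i]]
            while i + len(tied) < m and col[order[i + len(tied)]] == col[order[i]]:
                tied.append(order[i + len(tied)])
            avg = np.mean(range(i + 1, i + len(tied) + 1))
            for t in tied:
                r[t] = avg
            i += len(tied)
        ranks[:, j] = r
    R = ranks.sum(axis=1)
    chi = 12.0 / (k * m * (m + 1)) * np.sum(R**2) - 3 * k * (m + 1)
    ties = 0.0
    for j in range(k):
        _, counts = np.unique(acc[:, j], return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1 - ties / (k * (m**3 - m))
    if c <= 0:
        return 0.0
    return max(chi / c, 0.0)


# --------------------------------------------------------------------------


class TestConfusionCounts:
    def test_perfect_prediction(self):
        t = [1] * 6 + [0] * 4
        c = sc.confusion_counts(t, t)
        assert (c.TP, c.TN, c.FP, c.FN) == (6, 4, 0, 0)

    def test_all_predicted_positive(self):
        t = [1] * 6 + [0] * 4
        c = sc.confusion_counts(t, [1] * 10)
        assert (c.TP, c.FP, c.TN, c.FN) == (6, 4, 0, 0)

    def test_empty_vectors(self):
        c = sc.confusion_counts([], [])
        assert c.total == 0

    def test_string_labels_accepted(self):
        c = sc.confusion_counts(["true_site", "false_site"], ["true_site", "true_site"])
        assert (c.TP, c.FP) == (1, 1)

    def test_length_mismatch_raises(self):
        with pytest.raises(EvaluationError):
            sc.confusion_counts([1, 0], [1])

    def test_count_conservation_random(self):
        rng = np.random.default_rng(0)
        t, p = rng.integers(0, 2, 100), rng.integers(0, 2, 100)
        assert sc.confusion_counts(t, p).total == 100


class TestMetrics:
    def test_recall_example(self):
        m = sc.metrics(sc.ConfusionCounts(TP=3, TN=0, FP=0, FN=1))
        assert m.recall == pytest.approx(0.75)

    def test_accuracy_example(self):
        m = sc.metrics(sc.ConfusionCounts(TP=40, TN=40, FP=10, FN=10))
        assert m.accuracy == pytest.approx(0.80)

    def test_undefined_precision_flagged(self):
        m = sc.metrics(sc.ConfusionCounts(TP=0, TN=5, FP=0, FN=2))
        assert m.precision is None

    def test_perfect_counts_give_all_ones(self):
        m = sc.metrics(sc.ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert (m.recall, m.precision, m.accuracy, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_oracle_agreement_on_random_vectors(self):
        """Formulas match a brute-force oracle on 1,000 random label vectors."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 30)
            t = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = sc.confusion_counts(t, p)
            assert (c.TP, c.TN, c.FP, c.FN) == oracle_confusion(t, p)
            m = sc.metrics(c)
            for got, want in zip(
                (m.recall, m.precision, m.accuracy, m.f1), oracle_metrics(*oracle_confusion(t, p))
            ):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_percent_rendering(self):
        m = sc.metrics(sc.ConfusionCounts(TP=3, TN=1, FP=0, FN=1))
        pct = m.as_percent()
        assert pct["accuracy"] == 80.0
        assert pct["recall"] == 75.0


class TestFriedman:
    def test_all_tied_gives_zero_statistic(self):
        acc = np.full((4, 6), 0.9)
        res = sc.friedman_test(acc)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_strict_winner_mean_rank_one(self):
        rng = np.random.default_rng(1)
        acc = rng.uniform(0.5, 0.8, (5, 8))
        acc[2] = rng.uniform(0.9, 0.99, 8)  # algorithm 2 strictly best
        res = sc.friedman_test(acc)
        assert res.mean_ranks["alg3"] == 1.0

    def test_oracle_agreement_500_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            m = rng.integers(2, 9)
            k = rng.integers(2, 13)
            acc = rng.uniform(0.5, 1.0, (m, k))
            if rng.random() < 0.3:  # inject ties
                acc = np.round(acc, 1)
            res = sc.friedman_test(acc)
            assert res.statistic == pytest.approx(oracle_friedman(acc), abs=1e-9)

    def test_matches_scipy_friedmanchisquare(self):
        rng = np.random.default_rng(3)
        acc = rng.uniform(0.5, 1.0, (4, 10))
        res = sc.friedman_test(acc)
        # scipy treats each argument as one treatment measured over blocks
        stat, p = stats.friedmanchisquare(*[acc[i] for i in range(4)])
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(5)
        acc = np.round(rng.uniform(0.5, 1.0, (6, 9)), 1)
        table = rank_table(acc)
        m = acc.shape[0]
        np.testing.assert_allclose(table.ranks.sum(axis=0), m * (m + 1) / 2)

    def test_permutation_equivariance_and_shift_invariance(self):
        rng = np.random.default_rng(9)
        acc = rng.uniform(0.5, 1.0, (5, 7))
        base = sc.friedman_test(acc)
        perm = rng.permutation(5)
        permuted = sc.friedman_test(acc[perm])
        assert permuted.statistic == pytest.approx(base.statistic, abs=1e-9)
        mr_base = np.array(list(base.mean_ranks.values()))
        mr_perm = np.array(list(permuted.mean_ranks.values()))
        np.testing.assert_allclose(mr_perm, mr_base[perm], atol=1e-12)
        # adding a constant to one test's accuracies changes nothing
        shifted = acc.copy()
        shifted[:, 3] += 0.05
        assert sc.friedman_test(shifted).statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_too_small_raises(self):
        with pytest.raises(EvaluationError):
            sc.friedman_test(np.ones((1, 5)))

    def test_report_orders_by_mean_rank(self):
        acc = np.array([[0.7, 0.6], [0.9, 0.95], [0.5, 0.4]])
        rep = friedman_report(sc.friedman_test(acc))
        assert rep["Algorithm"].tolist() == ["alg2", "alg1", "alg3"]
        assert rep["Rank"].tolist() == [1, 2, 3]


class TestCrossOrganism:
    def test_matrix_shape_and_missing_errors(self, small_encoded):
        spec, w = sc.build_architecture("C1", seed=0)
        cfg = sc.SyntheticConfig(total=40, seed=1, organism="orgA")
        ds = sc.generate_dataset(cfg)
        acc, cells = sc.cross_organism_matrix({"orgA": (spec, w)}, {"orgA": ds, "orgB": ds})
        assert acc.shape == (1, 2)
        assert set(cells) == {("orgA", "orgA"), ("orgA", "orgB")}
        with pytest.raises(EvaluationError):
            sc.cross_organism_matrix({}, {"orgA": ds})
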