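import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from stresschip.expression import (
    ExpressionMatrix,
    filter_regulated,
    fold_changes,
    kmeans_patterns,
    length_regulation_correlation,
    read_expression,
    sample_dendrogram,
)
from stresschip.set_stats import GeneSet


def em(values: dict, genes=None):
    df = pd.DataFrame(values, index=genes or [f"g{i}" for i in range(len(next(iter(values.values()))))])
    return ExpressionMatrix(df)


class TestFoldChanges:
    def test_reference_dropped_and_differences_taken(self):
        m = em({"A": [1.0, 2.0], "B": [1.0, 3.0], "C": [0.0, 2.0]})
        fc = fold_changes(m)
        assert list(fc.columns) == ["B", "C"]
        assert fc.loc["g1", "B"] == 1.0  # a doubling
        assert fc.loc["g0", "B"] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            em({"B": [1.0]})

    def test_tsv_roundtrip(self, tmp_path):
        m = em({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        p = tmp_path / "e.tsv"
        m.to_tsv(p)
        back = read_expression(p)
        pd.testing.assert_frame_equal(back.values, m.values)


class TestFilterRegulated:
    def test_strictly_more_than_threshold(self):
        cut = math.log2(1.8)
        m = em({"A": [0.0, 0.0, 0.0], "B": [cut, cut + 1e-6, 0.9]})
        reg = filter_regulated(fold_changes(m))
        assert "g0" not in reg          # exactly 1.8-fold: excluded
        assert "g1" in reg              # just above
        assert "g2" in reg              # 2^0.9 ~ 1.866-fold

    def test_down_regulation_counts(self):
        m = em({"A": [0.0], "B": [-1.0]})
        assert "g0" in filter_regulated(fold_changes(m))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        m = em({"A": np.zeros(50), "B": rng.normal(0, 1.2, 50)})
        fc = fold_changes(m)
        loose = filter_regulated(fc, 1.5)
        tight = filter_regulated(fc, 2.5)
        assert tight.genes <= loose.genes

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            filter_regulated(pd.DataFrame({"B": [0.0]}), 1.0)


def _planted_fc(n_per=60, seed=0, amp=(2.0, -2.0, 1.5)):
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for ci, a in enumerate(amp, start=1):
        for _ in range(n_per):
            b = a + rng.normal(0, 0.15)
            d = (1.5 if ci == 3 else 0.0) + rng.normal(0, 0.15)
            rows.append([b, rng.normal(0, 0.15), d, rng.normal(0, 0.15)])
            truth.append(ci)
    fc = pd.DataFrame(rows, columns=list("BCDE"),
                      index=[f"g{i}" for i in range(len(rows))])
    return fc, pd.Series(truth, index=fc.index)


class TestKmeansPatterns:
    def test_recovers_planted_trajectories(self):
        fc, truth = _planted_fc()
        reg = GeneSet("r", frozenset(fc.index))
        labels, centers, sil = kmeans_patterns(fc, reg, seed=1)
        # map planted ids to recovered ids by majority and score accuracy
        acc = 0
        for ci in (1, 2, 3):
            sub = labels[truth == ci]
            acc += (sub == sub.mode().iloc[0]).sum()
        assert acc / len(labels) >= 0.98
        assert sil > 0.5

    def test_canonical_labels_order_by_condition_b(self):
        fc, truth = _planted_fc()
        reg = GeneSet("r", frozenset(fc.index))
        _, centers, _ = kmeans_patterns(fc, reg, seed=3)
        assert centers["B"].is_monotonic_decreasing

    def test_labels_stable_across_seeds(self):
        fc, _ = _planted_fc()
        reg = GeneSet("r", frozenset(fc.index))
        l1, _, _ = kmeans_patterns(fc, reg, seed=1)
        l2, _, _ = kmeans_patterns(fc, reg, seed=99)
        assert (l1 == l2).all()

    def test_duplicated_genes_get_identical_labels(self):
        fc, _ = _planted_fc(n_per=20)
        dup = fc.copy()
        dup.index = [f"d{i}" for i in range(len(dup))]
        both = pd.concat([fc, dup])
        reg = GeneSet("r", frozenset(both.index))
        labels, _, _ = kmeans_patterns(both, reg, seed=0)
        for i in range(len(fc)):
            assert labels[f"g{i}"] == labels[f"d{i}"]

    def test_k_one_single_cluster(self):
        fc, _ = _planted_fc(n_per=5)
        labels, _, _ = kmeans_patterns(fc, GeneSet("r", frozenset(fc.index)), k=1)
        assert set(labels) == {1}

    def test_k_exceeding_genes_rejected(self):
        fc, _ = _planted_fc(n_per=1)
        with pytest.raises(ValueError):
            kmeans_patterns(fc, GeneSet("r", frozenset(fc.index)), k=10)


def _children(link, labels):
    """Leaf-label sets of the two subtrees under the root, and sibling pairs."""
    tree = hierarchy.to_tree(link)
    def leaves(node):
        return {labels[i] for i in node.pre_order(lambda n: n.id)}
    pairs = []
    def walk(node):
        if node.is_leaf():
            return
        if node.left.is_leaf() and node.right.is_leaf():
            pairs.append({labels[node.left.id], labels[node.right.id]})
        walk(node.left), walk(node.right)
    walk(tree)
    return leaves(tree.left), leaves(tree.right), pairs


class TestSampleDendrogram:
    def _matrix(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1, size=n)
        cols = {
            "A": base + rng.normal(0, 0.1, n),
            "B": base + rng.normal(0, 0.1, n) + np.where(np.arange(n) < 60, 2.0, -2.0),
            "C": base + rng.normal(0, 0.1, n) + np.where(np.arange(n) < 60, 0.5, -0.5),
            "D": base + rng.normal(0, 0.1, n) + np.where(np.arange(n) % 3 == 0, 1.0, 0),
            "E": base + rng.normal(0, 0.1, n),
        }
        return ExpressionMatrix(pd.DataFrame(cols))

    def test_outlier_condition_isolated_first_and_calm_pair_sibling(self):
        m = self._matrix()
        reg = GeneSet("r", frozenset(m.genes))
        link, newick = sample_dendrogram(m, reg)
        left, right, pairs = _children(link, m.conditions)
        assert {"B"} in (left, right)
        assert {"A", "E"} in pairs
        assert newick.endswith(";") and "B" in newick

    def test_identical_conditions_merge_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        m = ExpressionMatrix(
            pd.DataFrame({"A": base, "B": base, "C": rng.normal(size=50)})
        )
        link, _ = sample_dendrogram(m, GeneSet("r", frozenset(m.genes)))
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_condition_at_maximal_height(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=80)
        m = ExpressionMatrix(
            pd.DataFrame({"A": base, "B": base + rng.normal(0, 0.05, 80), "C": -base})
        )
        link, _ = sample_dendrogram(m, GeneSet("r", frozenset(m.genes)))
        assert link[-1, 2] > 1.5  # 1 - r with r ~ -1 approaches 2

    def test_constant_column_error_names_condition(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 1.0, 1.0],
                          "C": [2.0, 1.0, 3.0]})
        )
        with pytest.raises(ValueError, match="'B'"):
            sample_dendrogram(m, GeneSet("r", frozenset(m.genes)))


class TestLengthRegulationCorrelation:
    def test_null_shows_no_correlation(self):
        rng = np.random.default_rng(0)
        n = 2000
        fc = pd.DataFrame({"B": rng.normal(0, 1, n)},
                          index=[f"g{i}" for i in range(n)])
        lengths = {f"g{i}": int(v) for i, v in
                   enumerate(rng.lognormal(7.2, 0.7, n))}
        res = length_regulation_correlation(fc, lengths)
        assert abs(res.rs) < 0.05

    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(1)
        n = 1000
        lengths = {f"g{i}": int(v) for i, v in
                   enumerate(rng.lognormal(7.2, 0.7, n))}
        fc = pd.DataFrame(
            {"B": [0.3 * math.log2(lengths[f"g{i}"]) + rng.normal(0, 0.3)
                   for i in range(n)]},
            index=list(lengths),
        )
        res = length_regulation_correlation(fc, lengths)
        assert res.rs > 0.3 and res.p_value < 1e-6

    def test_three_point_monotone(self):
        fc = pd.DataFrame({"B": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        lengths = {"a": 500, "b": 1500, "c": 4000}
        assert length_regulation_correlation(fc, lengths).rs == pytest.approx(1.0)
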