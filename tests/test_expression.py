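"""RPKM, the expression gate, DE calls, clustering, tissue restriction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncdiscover import (
    ExpressionMatrix,
    de_call,
    expressed_gate,
    hcluster,
    preprocess_for_clustering,
    rpkm,
    tissue_restriction,
)
from lncdiscover.expression import ExpressionError, _binom_two_sided

from oracles import brute_average_linkage, exact_binom_two_sided


def matrix(counts, libs, lengths, samples=None):
    counts = np.atleast_2d(np.asarray(counts))
    ids = [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(ids, samples, counts, np.asarray(libs), np.asarray(lengths))


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 2000, 1e7, 5.0), (0, 2000, 1e7, 0.0), (100, 2000, 2e7, 2.5)],
    )
    def test_closed_form(self, count, length, lib, expected):
        m = matrix([[count]], [lib], [length])
        assert rpkm(m).iloc[0, 0] == pytest.approx(expected, abs=0)

    def test_algebraic_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 1000, size=(5, 3))
        libs = rng.integers(1_000, 10_000, size=3).astype(float)
        lengths = rng.integers(200, 5_000, size=5).astype(float)
        base = rpkm(matrix(counts, libs, lengths)).to_numpy()
        doubled = rpkm(matrix(2 * counts, libs, lengths)).to_numpy()
        assert np.allclose(doubled, 2 * base)
        longer = rpkm(matrix(counts, libs, 2 * lengths)).to_numpy()
        assert np.allclose(longer, base / 2)
        deeper = rpkm(matrix(counts, 2 * libs, lengths)).to_numpy()
        assert np.allclose(deeper, base / 2)


class TestExpressedGate:
    def test_strict_inequality_boundary(self):
        table = pd.DataFrame(
            [[0.2, 0.3, 0.4, 0.2], [0.25, 0.25, 0.25, 0.25], [0, 0, 0, 0]],
            index=["above", "exactly_one", "zero"],
        )
        assert expressed_gate(table) == ["above"]

    def test_monotone_in_samples(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.uniform(0, 0.6, size=(20, 3)))
        wider = table.copy()
        wider[3] = rng.uniform(0, 0.6, size=20)
        assert set(expressed_gate(table)) <= set(expressed_gate(wider))


class TestDECall:
    def test_fold_direction_and_value(self):
        # mean RPKM 8 vs 2 (single-sample conditions)
        m = matrix([[800, 200]], [1e6, 1e6], [1000])
        (c,) = de_call(m, ["s0"], ["s1"])
        assert c.log2_fc == pytest.approx(2.0)
        assert c.direction == "up"

    def test_sub_threshold_and_swap_symmetry(self):
        m = matrix([[300, 200]], [1e6, 1e6], [1000])
        (c,) = de_call(m, ["s0"], ["s1"])
        (c_swapped,) = de_call(m, ["s1"], ["s0"])
        assert c.log2_fc == pytest.approx(np.log2(1.5), abs=1e-12)
        assert c.direction == "none"
        assert c_swapped.log2_fc == pytest.approx(-c.log2_fc, abs=0)

    def test_zero_versus_positive_is_infinite_and_de(self):
        m = matrix([[0, 10], [10, 0], [0, 0]], [1e6, 1e6], [1000, 1000, 1000])
        calls = de_call(m, ["s0"], ["s1"], fold_threshold=1e6)
        assert calls[0].log2_fc == -np.inf and calls[0].direction == "down"
        assert calls[1].log2_fc == np.inf and calls[1].direction == "up"
        assert calls[2].log2_fc == 0.0 and calls[2].direction == "none"

    def test_antisymmetry_property(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 500, size=(30, 4))
        m = matrix(counts, [1e6, 2e6, 1.5e6, 8e5], rng.integers(200, 3000, size=30))
        fwd = de_call(m, ["s0", "s1"], ["s2", "s3"])
        rev = de_call(m, ["s2", "s3"], ["s0", "s1"])
        for a, b in zip(fwd, rev):
            if np.isfinite(a.log2_fc):
                assert b.log2_fc == -a.log2_fc
            assert {a.direction, b.direction} in ({"none"}, {"up", "down"}) or (
                a.direction == "none" and b.direction == "none"
            )

    def test_binomial_example(self):
        # 0 vs 10 pooled counts with equal library sizes
        m = matrix([[0, 10]], [1e6, 1e6], [1000])
        (c,) = de_call(m, ["s0"], ["s1"], test="binomial")
        assert c.p_value == pytest.approx(2 * 0.5**10, abs=1e-15)

    @pytest.mark.parametrize(
        "k,n,p_num,p_den",
        [(0, 10, 1, 2), (3, 20, 3, 10), (7, 12, 1, 4), (25, 50, 2, 3), (0, 1, 1, 2)],
    )
    def test_binomial_matches_exact_rational_summation(self, k, n, p_num, p_den):
        got = _binom_two_sided(k, n, p_num / p_den)
        expected = float(exact_binom_two_sided(k, n, p_num, p_den))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_argument_errors(self):
        m = matrix([[1, 2]], [10, 10], [100])
        with pytest.raises(ExpressionError):
            de_call(m, [], ["s1"])
        with pytest.raises(ExpressionError):
            de_call(m, ["s0"], ["s0"])


class TestPreprocess:
    def test_closed_form_row(self):
        table = pd.DataFrame([[1.0, 3.0]], index=["a"])
        out = preprocess_for_clustering(table)
        assert np.allclose(out.to_numpy(), [[-np.sqrt(0.5), np.sqrt(0.5)]])

    def test_constant_row_dropped_with_warning(self):
        table = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 3.0, 7.0]], index=["flat", "var"])
        with pytest.warns(UserWarning, match="flat"):
            out = preprocess_for_clustering(table)
        assert list(out.index) == ["var"]

    def test_rows_are_centred_and_unit_norm(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.uniform(0, 50, size=(40, 6)))
        out = preprocess_for_clustering(table).to_numpy()
        assert np.abs(out.mean(axis=1)).max() < 1e-9
        assert np.abs((out**2).sum(axis=1) - 1).max() < 1e-9


class TestHCluster:
    def test_three_row_example(self):
        # A and B are perfectly correlated (d=0); C anti-correlated (d=2)
        x = np.array([[1, 2, 3], [2, 4, 6], [3, 2, 1]], dtype=float)
        tree = hcluster(x)
        (i0, j0, h0), (i1, j1, h1) = tree.merges
        assert (i0, j0) == (0, 1) and h0 == pytest.approx(0.0, abs=1e-12)
        assert (i1, j1) == (2, 3) and h1 == pytest.approx(2.0, abs=1e-12)
        assert tree.leaf_order == [2, 0, 1]

    def test_identical_rows_merge_at_zero(self):
        tree = hcluster(np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]]))
        assert tree.merges == [(0, 1, 0.0)]

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 5))
        scaled = x * rng.uniform(0.5, 10, size=(6, 1))
        a, b = hcluster(x), hcluster(scaled)
        assert [(i, j) for i, j, _ in a.merges] == [(i, j) for i, j, _ in b.merges]
        assert a.leaf_order == b.leaf_order

    @pytest.mark.parametrize("n_rows", [2, 3, 4, 5, 6])
    def test_matches_brute_force_recomputation(self, n_rows):
        rng = np.random.default_rng(100 + n_rows)
        x = rng.normal(size=(n_rows, 5))
        tree = hcluster(x)
        expected = brute_average_linkage(x)
        assert [(i, j) for i, j, _ in tree.merges] == [(i, j) for i, j, _ in expected]
        for (_, _, h), (_, _, he) in zip(tree.merges, expected):
            assert h == pytest.approx(he, abs=1e-9)
            assert h >= -1e-12

    def test_too_few_rows(self):
        with pytest.raises(ExpressionError):
            hcluster(np.array([[1.0, 2.0, 3.0]]))

    def test_dataframe_labels_in_leaf_order(self):
        table = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1]], index=["A", "B", "C"], dtype=float
        )
        assert hcluster(table).leaf_order == ["C", "A", "B"]


class TestTissueRestriction:
    def test_cases(self):
        table = pd.DataFrame(
            {
                "muscle": [10.0, 10.0, 0.5],
                "heart": [0.5, 5.0, 0.5],
                "liver": [0.2, 1.0, 0.5],
            },
            index=["restricted", "shared", "off"],
        )
        flags = tissue_restriction(table, "muscle")
        assert flags.tolist() == [True, False, False]

    def test_zero_elsewhere_passes_when_on(self):
        table = pd.DataFrame({"muscle": [10.0], "heart": [0.0]})
        assert tissue_restriction(table, "muscle").tolist() == [True]

    def test_unknown_tissue(self):
        table = pd.DataFrame({"muscle": [1.0], "heart": [1.0]})
        with pytest.raises(ExpressionError):
            tissue_restriction(table, "kidney")


def test_expression_matrix_tsv_round_trip(tmp_path):
    m = matrix([[10, 20], [0, 5]], [30.0, 60.0], [1000, 2000])
    path = tmp_path / "counts.tsv"
    m.to_tsv(path)
    lengths = dict(zip(m.transcript_ids, m.lengths))
    m2 = ExpressionMatrix.from_tsv(path, lengths)
    assert np.array_equal(m2.counts, m.counts)
    # library sizes default to column sums of the full table
    assert np.allclose(m2.library_sizes, [10, 25])
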