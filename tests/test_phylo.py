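"""Masking, gamma-corrected distances, NJ, bootstrap and Newick output."""

import numpy as np
import pandas as pd
import pytest

from srnase.phylo import (
    DistanceModel,
    MaskedAlignment,
    bootstrap_support,
    compute_distances,
    gamma_corrected_distance,
    leaf_distances,
    mask_low_coverage_columns,
    nj_tree,
    to_newick,
    write_newick,
)
from srnase.validation import nj_additive_consistency, random_additive_case


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_column_below_95_percent_coverage_is_removed():
    rows = ["A" * 5] * 18 + ["A-AAA", "A-AAA"]  # column 1: 18/20 = 0.90 coverage
    masked = mask_low_coverage_columns([f"s{i}" for i in range(20)], rows, 0.95)
    assert masked.kept_columns == [0, 2, 3, 4]


def test_gap_free_alignment_passes_untouched():
    rows = ["ACDEF", "ACDEG", "ACDEH"]
    masked = mask_low_coverage_columns(list("abc"), rows, 0.95)
    assert masked.rows == rows
    masked0 = mask_low_coverage_columns(list("abc"), rows, 1e-9)
    assert masked0.rows == rows


def test_fully_gapped_alignment_is_an_error():
    with pytest.raises(ValueError, match="all columns"):
        mask_low_coverage_columns(["a", "b"], ["--", "A-"], 0.95)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_gamma_correction_closed_form():
    alpha = 0.8
    expected = alpha * ((1 - 0.2) ** (-1 / alpha) - 1)
    assert gamma_corrected_distance(0.2, alpha) == pytest.approx(expected)
    assert gamma_corrected_distance(0.0, alpha) == 0.0


def test_distances_increase_monotonically_with_p():
    values = [gamma_corrected_distance(p, 0.8) for p in np.linspace(0.01, 0.9, 30)]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_identical_pair_is_zero_under_every_model():
    masked = MaskedAlignment(["a", "b"], ["MKVLW", "MKVLW"], list(range(5)), 0.95)
    for model in ("p-distance", "poisson-gamma", "jtt-gamma"):
        d = compute_distances(masked, DistanceModel(model))
        assert d.loc["a", "b"] == 0.0


def test_saturated_pair_hits_the_ceiling():
    masked = MaskedAlignment(["a", "b"], ["AAAA", "CCCC"], list(range(4)), 0.95)
    d = compute_distances(masked, DistanceModel("jtt-gamma", ceiling=10.0))
    assert d.loc["a", "b"] == 10.0


def test_ambiguous_columns_are_ignored_pairwise():
    masked = MaskedAlignment(["a", "b"], ["MKXLW", "MKWLW"], list(range(5)), 0.95)
    d = compute_distances(masked, DistanceModel("p-distance"))
    assert d.loc["a", "b"] == 0.0  # the only difference sits in an X column


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxon_branch_lengths_solve_the_three_point_formulas():
    m = pd.DataFrame(
        [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
    )
    tree = nj_tree(m)
    d = leaf_distances(tree)
    assert d["A"]["B"] == pytest.approx(5)
    assert d["A"]["C"] == pytest.approx(9)
    assert d["B"]["C"] == pytest.approx(10)


def test_nj_rejects_asymmetric_input():
    m = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC"), dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(m)


def test_nj_agrees_with_independent_implementation_on_random_matrices():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(4, 8))
        ids = [f"T{i}" for i in range(n)]
        arr = rng.uniform(1, 10, (n, n))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0)
        mine = nj_tree(pd.DataFrame(arr, index=ids, columns=ids)).bipartitions()
        sk_tree = skbio_nj(DistanceMatrix(arr, ids))
        anchor = min(ids)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(set(ids) - side)
            if 2 <= len(side) <= n - 2:
                theirs.add(side)
        assert mine == theirs


def test_nj_recovers_topology_on_additive_matrices():
    assert nj_additive_consistency(seed=17, n_instances=30) == 1.0


def test_additive_case_matrix_matches_its_splits():
    rng = np.random.default_rng(0)
    matrix, splits = random_additive_case(rng, 5)
    # four-point condition sanity on one quartet
    a, b, c, d = matrix.index[:4]
    sums = sorted(
        [
            matrix.loc[a, b] + matrix.loc[c, d],
            matrix.loc[a, c] + matrix.loc[b, d],
            matrix.loc[a, d] + matrix.loc[b, c],
        ]
    )
    assert sums[1] == pytest.approx(sums[2])
    assert len(splits) == 5 - 3  # n-3 internal edges on a binary tree


# ---------------------------------------------------------------------------
# bootstrap and newick
# ---------------------------------------------------------------------------

def _two_clade_alignment() -> MaskedAlignment:
    rng = np.random.default_rng(5)
    core_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
    core_b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
    def noisy(core, k):
        s = list(core)
        for pos in rng.choice(60, size=k, replace=False):
            s[pos] = "A" if s[pos] != "A" else "C"
        return "".join(s)
    rows = [noisy(core_a, 2), noisy(core_a, 2), noisy(core_b, 2), noisy(core_b, 2)]
    return MaskedAlignment(["a1", "a2", "b1", "b2"], rows, list(range(60)), 0.95)


def test_deep_split_receives_high_bootstrap_support():
    tree = bootstrap_support(_two_clade_alignment(), DistanceModel("p-distance"), 100, seed=3)
    supports = [n.support for n in _internal(tree) if n.support is not None]
    assert supports and max(supports) >= 95.0


def test_single_replicate_supports_are_zero_or_hundred():
    tree = bootstrap_support(_two_clade_alignment(), DistanceModel("p-distance"), 1, seed=3)
    for node in _internal(tree):
        if node.support is not None:
            assert node.support in (0.0, 100.0)


def test_bootstrap_is_seed_reproducible():
    t1 = bootstrap_support(_two_clade_alignment(), n_replicates=25, seed=9)
    t2 = bootstrap_support(_two_clade_alignment(), n_replicates=25, seed=9)
    assert to_newick(t1) == to_newick(t2)


def _internal(tree):
    out = []
    stack = list(tree.root.children)
    while stack:
        n = stack.pop()
        if n.children:
            out.append(n)
            stack.extend(n.children)
    return out


def test_newick_round_trips_through_dendropy(tmp_path):
    import dendropy

    tree = bootstrap_support(_two_clade_alignment(), n_replicates=10, seed=1)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == ["a1", "a2", "b1", "b2"]
    text = path.read_text()
    assert text.startswith("(") and text.strip().endswith(";")
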