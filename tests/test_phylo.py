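"""Distances, neighbor joining, bootstrap, Fitch parsimony, CI/RI."""

import numpy as np
import pytest

from b73prov import phylo
from _util import (
    dendropy_nj,
    exhaustive_parsimony,
    make_matrix,
    patristic_distance_matrix,
    random_additive_tree,
)


# ---------------------------------------------------------------------------
# distances

def test_distance_trivial_cases():
    m = make_matrix([[0, 0, 2, 1], [2, 2, 0, 1], [1, 1, 2, 1]],
                    samples=["a", "b", "c", "d"])
    dm = phylo.pairwise_distance(m)
    i = {s: k for k, s in enumerate(dm.samples)}
    assert dm.d[i["a"], i["b"]] == 0.0          # identical samples
    assert dm.d[i["a"], i["c"]] == pytest.approx((1 + 1 + 0.5) / 3)
    # HOM_REF vs HET at every site -> 0.5
    m2 = make_matrix([[0, 1], [0, 1], [0, 1]])
    assert phylo.pairwise_distance(m2).d[0, 1] == 0.5
    # HOM_REF vs HOM_ALT at every site -> 1 (maximum)
    m3 = make_matrix([[0, 2], [0, 2]])
    assert phylo.pairwise_distance(m3).d[0, 1] == 1.0


def test_distance_errors_name_the_pair():
    m = make_matrix([[0, -1], [-1, 2]], samples=["left", "right"])
    with pytest.raises(ValueError, match="left.*right"):
        phylo.pairwise_distance(m)


def test_distance_skips_sites_missing_in_either_sample():
    m = make_matrix([[0, 2], [0, -1], [-1, 2], [0, 0]])
    dm = phylo.pairwise_distance(m)
    assert dm.n_shared[0, 1] == 2
    assert dm.d[0, 1] == 0.5  # one of two shared sites differs fully


# ---------------------------------------------------------------------------
# neighbor joining

@pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (7, 2), (10, 3), (10, 4)])
def test_nj_recovers_random_additive_trees_exactly(n, seed):
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n)]
    true = random_additive_tree(rng, labels)
    dm = patristic_distance_matrix(true, labels)
    mine = phylo.neighbor_joining(dm)
    assert phylo.rf_distance(true, mine) == 0
    # additive input: branch lengths reproduce the input metric exactly
    d2 = patristic_distance_matrix(mine, labels).d
    assert np.allclose(dm.d, d2, atol=1e-9)
    # independent oracle route agrees on topology
    oracle = dendropy_nj(dm)
    assert phylo.rf_distance(mine, oracle) == 0


def test_nj_three_taxa_star_lengths():
    d = np.array([[0, 2.0, 3.0], [2.0, 0, 3.0], [3.0, 3.0, 0]])
    dm = phylo.DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), dtype=np.int64))
    tree = phylo.neighbor_joining(dm)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 2.0})


def test_nj_invariant_to_sample_order():
    rng = np.random.default_rng(9)
    labels = [f"t{i}" for i in range(8)]
    true = random_additive_tree(rng, labels)
    dm = patristic_distance_matrix(true, labels)
    perm = list(rng.permutation(8))
    dm_p = phylo.DistanceMatrix(
        [labels[i] for i in perm], dm.d[np.ix_(perm, perm)],
        dm.n_shared[np.ix_(perm, perm)],
    )
    assert phylo.rf_distance(
        phylo.neighbor_joining(dm), phylo.neighbor_joining(dm_p)
    ) == 0


def test_nj_rejects_nonfinite_and_tiny_inputs():
    bad = np.array([[0, np.inf], [np.inf, 0]])
    with pytest.raises(ValueError):
        phylo.neighbor_joining(
            phylo.DistanceMatrix(["a", "b"], bad, np.ones((2, 2), dtype=np.int64))
        )


# ---------------------------------------------------------------------------
# bootstrap

def _caterpillar_matrix(n_sites=999):
    """Six samples, three nested compatible splits, no conflicting signal."""
    patterns = [
        [0, 0, 2, 2, 2, 2],
        [0, 0, 0, 2, 2, 2],
        [0, 0, 0, 0, 2, 2],
    ]
    rows = [patterns[i % 3] for i in range(n_sites)]
    return make_matrix(rows)


def test_bootstrap_support_is_100_without_conflict():
    m = _caterpillar_matrix()
    tree = phylo.bootstrap_support(m, n_reps=50, seed=11)
    supports = [
        int(node.label)
        for node in tree.preorder_internal_node_iter()
        if node is not tree.seed_node and node.label is not None
    ]
    assert supports and all(s == 100 for s in supports)


def test_bootstrap_is_deterministic_given_seed():
    m = _caterpillar_matrix(300)
    t1 = phylo.bootstrap_support(m, n_reps=20, seed=5)
    t2 = phylo.bootstrap_support(m, n_reps=20, seed=5)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


# ---------------------------------------------------------------------------
# Fitch parsimony and CI/RI

def _quartet(newick):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick")


def test_fitch_simple_patterns():
    tree = _quartet("((A,B),(C,D));")
    m = make_matrix(
        [[0, 0, 2, 2],      # AABB on ((A,A),(B,B)) -> 1 change
         [0, 2, 0, 2],      # ABAB -> 2 changes
         [-1, -1, -1, -1]],  # all missing -> 0
        samples=["A", "B", "C", "D"],
    )
    total, per_site = phylo.fitch_score(m, tree)
    assert per_site.tolist() == [1, 2, 0]
    assert total == 3


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fitch_equals_exhaustive_minimum(seed):
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(6)]
    tree = random_additive_tree(rng, labels)
    calls = rng.integers(-1, 3, size=(12, 6))
    m = make_matrix(calls, samples=labels)
    _, per_site = phylo.fitch_score(m, tree)
    for i in range(m.n_sites):
        states = {
            lab: (None if calls[i, j] < 0 else int(calls[i, j]))
            for j, lab in enumerate(labels)
        }
        assert per_site[i] == exhaustive_parsimony(tree, states), f"site {i}"


def test_ci_ri_known_values():
    tree = _quartet("((A,B),(C,D));")
    # homoplasy-free: AABB pattern fits the tree perfectly
    clean = make_matrix([[0, 0, 2, 2]] * 5, samples=["A", "B", "C", "D"])
    ci, ri = phylo.consistency_retention(clean, tree)
    assert (ci, ri) == (1.0, 1.0)
    # single ABAB site: m=1, s=2 -> CI=0.5; g=2 -> RI=0
    conflict = make_matrix([[0, 2, 0, 2]], samples=["A", "B", "C", "D"])
    ci, ri = phylo.consistency_retention(conflict, tree)
    assert ci == 0.5
    assert ri == 0.0


def test_ri_invariant_to_site_duplication():
    rng = np.random.default_rng(7)
    labels = [f"t{i}" for i in range(6)]
    tree = random_additive_tree(rng, labels)
    m = make_matrix(rng.integers(0, 3, size=(20, 6)), samples=labels)
    doubled = make_matrix(
        np.repeat(m.calls, 2, axis=0), samples=labels,
        positions=[100 * (i + 1) for i in range(40)],
    )
    ci1, ri1 = phylo.consistency_retention(m, tree)
    ci2, ri2 = phylo.consistency_retention(doubled, tree)
    assert ci1 == pytest.approx(ci2)
    assert ri1 == pytest.approx(ri2)


def test_invariant_matrix_ci_is_one_by_convention():
    m = make_matrix([[0, 0, 0, 0]], samples=["A", "B", "C", "D"])
    ci, _ = phylo.consistency_retention(m, _quartet("((A,B),(C,D));"))
    assert ci == 1.0
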