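"""Distance and parsimony phylogenetics over genotype matrices.

Pairwise allele-sharing distances, neighbor joining (Saitou-Nei), bootstrap
support over site resampling, Fitch small parsimony and the consistency /
retention indices.  Trees are :class:`dendropy.Tree` objects throughout;
bootstrap percentages are stored as internal-node labels, the standard Newick
convention.

Neighbor joining stands in for maximum-likelihood inference here: for clade
recovery on SNP matrices of this scale it is deterministic, fast and
consistent on additive distances, which is the property the downstream
analyses rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .genotyping import GenotypeMatrix

logger = logging.getLogger(__name__)

_STATE_MASK = {0: 1, 1: 2, 2: 4, -1: 7}  # bitmask alphabet; MISSING = all states


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.d.shape != (n, n) or self.n_shared.shape != (n, n):
            raise ValueError("matrix shapes do not match sample count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(self.d).any():
            raise ValueError("self-distances must be zero")


def _distances_from_calls(calls: np.ndarray, samples: list[str]) -> DistanceMatrix:
    """Allele-sharing distance: mean over co-genotyped sites of
    |dosage_i - dosage_j| / 2, in [0, 1]."""
    n = calls.shape[1]
    valid = calls >= 0
    d = np.zeros((n, n))
    n_shared = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(n_shared, valid.sum(axis=0))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            ns = int(both.sum())
            n_shared[i, j] = n_shared[j, i] = ns
            if ns == 0:
                raise ValueError(
                    f"no co-genotyped sites for pair ({samples[i]}, {samples[j]})"
                )
            diff = np.abs(
                calls[both, i].astype(np.int16) - calls[both, j].astype(np.int16)
            )
            d[i, j] = d[j, i] = float(diff.mean()) / 2.0
    return DistanceMatrix(samples, d, n_shared)


def pairwise_distance(m: GenotypeMatrix) -> DistanceMatrix:
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return _distances_from_calls(m.calls, m.samples)


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei agglomeration.  Negative branch lengths are clamped to 0;
    ties in the Q criterion break to the earliest-created node pair, so the
    result is deterministic."""
    n = len(dm.samples)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    node_of: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.require_taxon(label=s))
        for i, s in enumerate(dm.samples)
    }
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        idx = np.array(active)
        Dsub = D[np.ix_(idx, idx)]
        r = len(active)
        rs = Dsub.sum(axis=1)
        Q = (r - 2) * Dsub - rs[:, None] - rs[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        cands = [(a, b) for a, b in cands if a < b]
        a, b = min(cands)
        i, j = active[a], active[b]
        li = 0.5 * D[i, j] + (rs[a] - rs[b]) / (2 * (r - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        u.add_child(node_of[i])
        node_of[i].edge.length = max(li, 0.0)
        u.add_child(node_of[j])
        node_of[j].edge.length = max(lj, 0.0)
        for k in active:
            if k not in (i, j):
                D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        node_of[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = tree.seed_node
    for k, lk in ((x, lx), (y, ly), (z, lz)):
        root.add_child(node_of[k])
        node_of[k].edge.length = max(lk, 0.0)
    tree.is_rooted = False
    return tree


def _internal_splits(tree: dendropy.Tree) -> dict[int, dendropy.Edge]:
    """Normalized split bitmask -> edge, for internal (non-trivial) edges."""
    tree.encode_bipartitions()
    out = {}
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        out[edge.bipartition.split_bitmask] = edge
    return out


def bootstrap_support(
    m: GenotypeMatrix, n_reps: int = 100, seed: int = 0
) -> dendropy.Tree:
    """NJ tree from the full matrix with internal edges annotated by the
    percentage of site-resampled replicates containing the same bipartition.

    Replicates in which some sample pair shares no genotyped sites are
    skipped with a warning; percentages are taken over completed replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tns = dendropy.TaxonNamespace()
    full = neighbor_joining(pairwise_distance(m), taxon_namespace=tns)
    splits = _internal_splits(full)
    counts = {mask: 0 for mask in splits}
    rng = np.random.default_rng(seed)
    completed = 0
    for rep in range(n_reps):
        idx = rng.integers(0, m.n_sites, m.n_sites)
        try:
            dm = _distances_from_calls(m.calls[idx], m.samples)
        except ValueError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", rep, exc)
            continue
        rep_tree = neighbor_joining(dm, taxon_namespace=tns)
        rep_masks = set(_internal_splits(rep_tree))
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
        completed += 1
    if completed == 0:
        raise ValueError("all bootstrap replicates failed")
    for mask, edge in splits.items():
        edge.head_node.label = str(round(100 * counts[mask] / completed))
    return full


def split_support(tree: dendropy.Tree, labels: set[str]) -> int | None:
    """Bootstrap percentage of the (unrooted) split separating ``labels``
    from the rest, or None if the tree does not contain that split."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    target = frozenset(labels)
    complement = frozenset(all_labels - labels)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below in (target, complement):
            return int(node.label) if node.label is not None else None
    return None


def has_split(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True if ``labels`` form one side of some edge of the unrooted tree."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    target = frozenset(labels)
    complement = frozenset(all_labels - labels)
    if len(target) <= 1 or len(complement) <= 1:
        return True  # trivial split, always present
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below in (target, complement):
            return True
    return False


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (clones both trees onto a common
    taxon namespace)."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def _leaf_masks(m: GenotypeMatrix, tree: dendropy.Tree) -> dict[dendropy.Node, np.ndarray]:
    cols = {s: j for j, s in enumerate(m.samples)}
    masks = {}
    lut = np.array([7, 1, 2, 4], dtype=np.int8)  # index by call+1
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label not in cols:
            raise ValueError(f"tree leaf {label!r} not among matrix samples")
        masks[leaf] = lut[m.calls[:, cols[label]].astype(np.int16) + 1]
    if len(masks) != m.n_samples:
        raise ValueError("tree leaves do not cover all matrix samples")
    return masks


def fitch_score(m: GenotypeMatrix, tree: dendropy.Tree) -> tuple[int, np.ndarray]:
    """Per-site Fitch small-parsimony change counts over states {0,1,2};
    MISSING leaves allow all states.

    Children at multifurcating nodes are folded sequentially, which is exact
    for binary trees and for the trifurcating root of an unrooted NJ tree.
    """
    masks = _leaf_masks(m, tree)
    changes = np.zeros(m.n_sites, dtype=np.int64)
    state: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[node] = masks[node]
            continue
        children = node.child_nodes()
        acc = state[children[0]]
        for child in children[1:]:
            inter = acc & state[child]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | state[child], inter)
        state[node] = acc
    return int(changes.sum()), changes


def consistency_retention(
    m: GenotypeMatrix, tree: dendropy.Tree
) -> tuple[float, float]:
    """Consistency and retention indices of a genotype matrix on a tree.

    Per site: m_i = observed states - 1 (minimum changes on any tree),
    s_i = Fitch changes, g_i = non-missing leaves minus the count of the most
    frequent state (changes on a star tree).  CI = sum(m)/sum(s); RI uses
    only sites with g_i != m_i (parsimony-informative for retention).
    """
    _, s = fitch_score(m, tree)
    counts = np.stack([(m.calls == c).sum(axis=1) for c in (0, 1, 2)])
    n_states = (counts > 0).sum(axis=0)
    m_i = np.maximum(n_states - 1, 0)
    n_nonmiss = counts.sum(axis=0)
    g_i = np.where(n_nonmiss > 0, n_nonmiss - counts.max(axis=0), 0)
    sum_s = int(s.sum())
    if sum_s == 0:
        logger.info("no changes on tree; CI reported as 1.0 by convention")
        ci = 1.0
    else:
        ci = float(m_i.sum() / sum_s)
    informative = g_i != m_i
    denom = float(g_i[informative].sum() - m_i[informative].sum())
    if denom <= 0:
        ri = 1.0
    else:
        ri = float((g_i[informative].sum() - s[informative].sum()) / denom)
    return ci, ri
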