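"""Shared test helpers: small matrices, random additive trees, oracles."""

from __future__ import annotations

import io as _io
from itertools import product

import dendropy
import numpy as np
import pandas as pd

from b73prov import synth
from b73prov.genotyping import GenotypeMatrix
from b73prov.model import GenomicInterval, SITE_COLUMNS
from b73prov.phylo import DistanceMatrix


def make_matrix(
    calls, samples=None, chrom="1", positions=None, ref="A", alt="T"
) -> GenotypeMatrix:
    """GenotypeMatrix from a nested list (sites x samples) of -1/0/1/2."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_sites)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": ref, "alt": alt},
        columns=SITE_COLUMNS,
    )
    return GenotypeMatrix(sites, samples, calls)


def flat_lineage() -> synth.Clade:
    """Three flat clades (no subclades): at reduced site counts every clade
    edge still carries enough private signal to be recoverable.  Subclade
    resolution at study scale is exercised on the default configuration."""
    return synth.Clade("root", children=[
        synth.Clade("USA_South", 12),
        synth.Clade("North_group", children=[
            synth.Clade("USA_North", 5),
            synth.Clade("China", 3),
        ]),
    ])


def small_sim_config(seed=0, **overrides) -> synth.SimConfig:
    """A scaled-down simulation for fast unit tests."""
    defaults = dict(
        n_chromosomes=6,
        chrom_length=30_000_000,
        n_sites=1_500,
        n_genes=2_500,
        lineage_spec=flat_lineage(),
        internal_branch_weight=1.0,
        introgressions=[
            synth.Introgression("China", GenomicInterval("2", 5_000_000, 9_000_000), 0),
            synth.Introgression("North_group", GenomicInterval("5", 12_000_000, 20_000_000), 1),
        ],
        n_donors=12,
        seed=seed,
    )
    defaults.update(overrides)
    return synth.SimConfig(**defaults)


def random_additive_tree(rng: np.random.Generator, labels: list[str]) -> dendropy.Tree:
    """Random unrooted binary tree with positive branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=l)) for l in labels]
    for nd in nodes:
        nd.edge.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.is_rooted = False
    return tree


def patristic_distance_matrix(tree: dendropy.Tree, labels: list[str]) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d, np.full((n, n), 1, dtype=np.int64))


def dendropy_nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Independent NJ oracle via dendropy's own implementation."""
    buf = "," + ",".join(dm.samples) + "\n"
    for i, s in enumerate(dm.samples):
        buf += s + "," + ",".join(str(x) for x in dm.d[i]) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        _io.StringIO(buf), delimiter=","
    )
    return pdm.nj_tree()


def exhaustive_parsimony(tree: dendropy.Tree, leaf_states: dict[str, int | None]) -> int:
    """Minimum changes over all internal-state assignments (and all states of
    missing leaves); brute force, for <= 6 taxa."""
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    free_leaves = [
        n for n in nodes if n.is_leaf() and leaf_states[n.taxon.label] is None
    ]
    best = np.inf
    for assign in product((0, 1, 2), repeat=len(internal) + len(free_leaves)):
        st = dict(zip(internal + free_leaves, assign))
        for n in nodes:
            if n.is_leaf() and n not in st:
                st[n] = leaf_states[n.taxon.label]
        cost = sum(
            1
            for n in nodes
            if n.parent_node is not None and st[n] != st[n.parent_node]
        )
        best = min(best, cost)
    return int(best)


def oracle_classify(r: int, a: int, o: int, min_depth: int = 5) -> str:
    """Exact integer-arithmetic restatement of the genotype-calling rules
    (depth < 5 missing; >=99% one allele homozygous; ref+alt > 90% with each
    allele > 20% heterozygous; otherwise missing)."""
    total = r + a + o
    if total < min_depth:
        return "MISSING"
    if 100 * a >= 99 * total:
        return "HOM_ALT"
    if 100 * r >= 99 * total:
        return "HOM_REF"
    if 10 * (r + a) > 9 * total and 5 * r > total and 5 * a > total:
        return "HET"
    return "MISSING"
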