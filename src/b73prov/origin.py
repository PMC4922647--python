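"""Donor-origin assignment of haplotype blocks against a reference panel.

For each named block, a consensus genotype vector from its carrier samples is
compared to a panel of donor haplotypes: the nearest haplotype by
allele-sharing distance, an NJ placement of the consensus among the panel
(the consensus' terminal branch length summarizes its divergence from the
panel), and a k-means (k = 2) partition of samples plus panel members as an
orthogonal check that carriers and donor fall in one cluster.

Missing data is filled by k-nearest-neighbour majority imputation on global
allele-sharing similarity — a deliberately simple analogue of LD-kNNi
imputers, adequate at ~10k sites where genome-wide similarity already
separates the lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import phylo
from .genotyping import GenotypeMatrix
from .model import GenomicInterval

logger = logging.getLogger(__name__)


class PanelMatrix(GenotypeMatrix):
    """Genotype matrix whose columns are donor panel haplotypes."""

    @property
    def haplotypes(self) -> list[str]:
        return self.samples


@dataclass
class OriginReport:
    block_id: str
    query: str
    closest: list[str]
    distance: float
    branch_length: float | None = None
    tie: bool = False
    cluster_partition: tuple[frozenset, frozenset] | None = None

    @property
    def no_single_best_match(self) -> bool:
        return self.tie


def _align_panel(
    m_sites: pd.DataFrame, consensus: np.ndarray, panel: PanelMatrix, region: GenomicInterval
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict consensus + panel to shared (chrom, pos) sites in the region.

    Returns (consensus subvector, panel submatrix) with aligned rows.
    """
    if len(m_sites) != len(consensus):
        raise ValueError("consensus length does not match site table")
    q = m_sites.reset_index(drop=True).copy()
    q["_qi"] = np.arange(len(q))
    p = panel.sites.reset_index(drop=True).copy()
    p["_pi"] = np.arange(len(p))
    merged = q.merge(p, on=["chrom", "pos"], suffixes=("_q", "_p"))
    merged = merged[
        (merged["chrom"] == region.chrom)
        & (merged["pos"] >= region.start)
        & (merged["pos"] <= region.stop)
    ]
    if merged.empty:
        raise ValueError("no shared sites between query and panel in region")
    qi = merged["_qi"].to_numpy()
    pi = merged["_pi"].to_numpy()
    return consensus[qi], panel.calls[pi]


def nearest_haplotype(
    consensus: np.ndarray,
    consensus_sites: pd.DataFrame,
    panel: PanelMatrix,
    region: GenomicInterval,
) -> tuple[list[str], float]:
    """Closest panel haplotype(s) to a consensus call vector inside a region.

    Returns (names, distance); more than one name means no single best match.
    Distances are allele-sharing distances over shared non-missing sites.
    """
    cvec, pcalls = _align_panel(consensus_sites, consensus, panel, region)
    dists = np.full(len(panel.haplotypes), np.nan)
    for j in range(pcalls.shape[1]):
        both = (cvec >= 0) & (pcalls[:, j] >= 0)
        if not both.any():
            continue
        dists[j] = float(
            np.abs(cvec[both].astype(np.int16) - pcalls[both, j].astype(np.int16)).mean() / 2.0
        )
    if np.isnan(dists).all():
        raise ValueError("no panel haplotype shares genotyped sites with the query")
    best = np.nanmin(dists)
    names = [
        panel.haplotypes[j]
        for j in range(len(dists))
        if not np.isnan(dists[j]) and dists[j] <= best + 1e-12
    ]
    return names, float(best)


def place_in_panel_tree(
    consensus_vectors: dict[str, np.ndarray],
    consensus_sites: pd.DataFrame,
    panel: PanelMatrix,
    region: GenomicInterval,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """NJ tree over panel haplotypes plus query consensus vectors, restricted
    to the region; returns the tree and each query's terminal branch length."""
    names = list(panel.haplotypes)
    aligned_q = {}
    pcalls_ref = None
    for qname, vec in consensus_vectors.items():
        cvec, pcalls = _align_panel(consensus_sites, vec, panel, region)
        aligned_q[qname] = cvec
        pcalls_ref = pcalls
    if pcalls_ref is None:
        raise ValueError("no consensus vectors given")
    cols = [pcalls_ref[:, j] for j in range(pcalls_ref.shape[1])]
    all_names = names + list(aligned_q)
    calls = np.column_stack(cols + [aligned_q[q] for q in aligned_q])
    dm = phylo._distances_from_calls(calls.astype(np.int8), all_names)
    tree = phylo.neighbor_joining(dm)
    terminal = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in aligned_q:
            terminal[leaf.taxon.label] = float(leaf.edge.length or 0.0)
    return tree, terminal


def impute_missing(m: GenotypeMatrix, k: int = 3, seed: int = 0) -> GenotypeMatrix:
    """Fill MISSING calls by majority vote of the k globally most similar
    samples that are genotyped at the site.

    Similarity is 1 - allele-sharing distance over all co-genotyped sites.
    The default k is small and odd: the vote must not be dominated by
    out-of-lineage neighbours when the smallest clade in a cohort has only a
    few members, and an odd neighbour count avoids two-way ties.
    Cells with no genotyped neighbours fall back to the site's most frequent
    call, then to HOM_REF (logged).  Observed calls are never altered; the
    ``seed`` argument is accepted for interface symmetry (the procedure is
    deterministic).
    """
    del seed  # deterministic; kept for a uniform stage interface
    out = m.calls.copy()
    if not (out == -1).any():
        return GenotypeMatrix(m.sites, m.samples, out)
    dm = phylo.pairwise_distance(m)
    counts = np.stack([(m.calls == c).sum(axis=1) for c in (0, 1, 2)])
    site_majority = counts.argmax(axis=0).astype(np.int8)
    site_empty = counts.sum(axis=0) == 0
    if site_empty.any():
        logger.warning(
            "%d all-missing sites imputed as HOM_REF", int(site_empty.sum())
        )
    site_majority[site_empty] = 0
    for j in range(m.n_samples):
        order = np.argsort(dm.d[j], kind="stable")
        order = order[order != j]
        missing_rows = np.where(out[:, j] == -1)[0]
        if len(missing_rows) == 0:
            continue
        neighbor_calls = m.calls[np.ix_(missing_rows, order)]
        for r, row in enumerate(neighbor_calls):
            observed = row[row >= 0][:k]
            if len(observed) == 0:
                out[missing_rows[r], j] = site_majority[missing_rows[r]]
                continue
            vals, cnts = np.unique(observed, return_counts=True)
            out[missing_rows[r], j] = np.int8(vals[np.argmax(cnts)])
    return GenotypeMatrix(m.sites, m.samples, out)


def kmeans_validation(
    m: GenotypeMatrix,
    panel: PanelMatrix,
    region: GenomicInterval,
    seed: int = 0,
    panel_haplotypes: list[str] | None = None,
) -> tuple[frozenset, frozenset]:
    """k-means (k = 2, 10 restarts) over samples plus selected panel
    haplotypes on 0/1/2-coded calls inside the region.

    Residual missing values are filled with the per-site majority over the
    pooled points before clustering.
    """
    region_idx = np.where(m.region_mask(region))[0]
    if len(region_idx) < 2:
        raise ValueError("region must contain at least 2 sites")
    hap_names = panel_haplotypes if panel_haplotypes is not None else panel.haplotypes
    sub_sites = m.sites.loc[region_idx]
    merged = (
        sub_sites.reset_index()
        .rename(columns={"index": "_qi"})
        .merge(
            panel.sites.reset_index().rename(columns={"index": "_pi"}),
            on=["chrom", "pos"],
            suffixes=("_q", "_p"),
        )
    )
    if merged.empty:
        raise ValueError("no shared sites between matrix and panel in region")
    qi = merged["_qi"].to_numpy()
    pi = merged["_pi"].to_numpy()
    hap_idx = [panel.sample_index(h) for h in hap_names]
    points = np.vstack(
        [m.calls[qi][:, [m.sample_index(s) for s in m.samples]].T,
         panel.calls[pi][:, hap_idx].T]
    ).astype(float)
    labels_all = list(m.samples) + list(hap_names)
    # fill residual missing with pooled per-site majority
    for col in range(points.shape[1]):
        vals = points[:, col]
        miss = vals < 0
        if miss.any():
            observed = vals[~miss]
            fill = 0.0
            if len(observed):
                u, c = np.unique(observed, return_counts=True)
                fill = float(u[np.argmax(c)])
            vals[miss] = fill
    if np.unique(points, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct points; k-means undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % (2**31))
    assign = km.fit_predict(points)
    a = frozenset(l for l, c in zip(labels_all, assign) if c == 0)
    b = frozenset(l for l, c in zip(labels_all, assign) if c == 1)
    return a, b
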