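"""Detection and summary of dense non-reference haplotype blocks.

A sample's non-reference calls (HOM_ALT or HET) are clustered per chromosome
by single-linkage on genomic distance: consecutive non-reference SNPs no more
than ``max_gap`` bp apart belong to one cluster, and clusters with at least
``min_snps`` members become blocks spanning their first to last SNP.  This is
a transparent, parameter-light replacement for visual identification of
megabase-scale introgression blocks against a sparse background of private
SNPs.

Per-sample blocks that overlap across samples are merged into regions; a
region observed in two or more carriers is named ``c{chrom}r{rank}`` in
chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotyping import GenotypeCall, GenotypeMatrix
from .model import GenomicInterval


@dataclass
class HaplotypeBlock:
    id: str
    interval: GenomicInterval
    carriers: set[str]
    n_snps: int
    carrier_zygosity: dict[str, str] = field(default_factory=dict)
    carrier_intervals: dict[str, GenomicInterval] = field(default_factory=dict)


@dataclass(frozen=True)
class BlockParams:
    min_snps: int = 5
    max_gap: int = 2_000_000
    carrier_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if not 0.0 < self.carrier_frac <= 1.0:
            raise ValueError("carrier_frac must be in (0, 1]")


def detect_blocks(
    m: GenotypeMatrix, sample: str, p: BlockParams = BlockParams()
) -> list[HaplotypeBlock]:
    """Cluster one sample's non-reference sites into haplotype blocks."""
    j = m.sample_index(sample)
    calls = m.calls[:, j]
    nonref = (calls == GenotypeCall.HOM_ALT) | (calls == GenotypeCall.HET)
    blocks: list[HaplotypeBlock] = []
    k = 0
    for chrom, grp in m.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        idx = idx[nonref[idx]]
        if len(idx) == 0:
            continue
        pos = m.sites["pos"].to_numpy()[idx]
        breaks = np.where(np.diff(pos) > p.max_gap)[0] + 1
        for cluster in np.split(np.arange(len(pos)), breaks):
            if len(cluster) < p.min_snps:
                continue
            members = idx[cluster]
            het_frac = float((calls[members] == GenotypeCall.HET).mean())
            k += 1
            blocks.append(
                HaplotypeBlock(
                    id=f"{sample}.b{k}",
                    interval=GenomicInterval(chrom, int(pos[cluster[0]]), int(pos[cluster[-1]])),
                    carriers={sample},
                    n_snps=len(members),
                    carrier_zygosity={sample: "HET" if het_frac > 0.5 else "HOM"},
                )
            )
    return blocks


def _carrier_stats(
    m: GenotypeMatrix, region: GenomicInterval, sample: str
) -> tuple[int, int, int]:
    """(genotyped sites, non-reference sites, heterozygous sites) for a
    sample inside a region."""
    mask = m.region_mask(region)
    calls = m.calls[mask, m.sample_index(sample)]
    genotyped = int((calls >= 0).sum())
    nonref = int(((calls == 1) | (calls == 2)).sum())
    het = int((calls == 1).sum())
    return genotyped, nonref, het


def merge_blocks_across_samples(
    per_sample: list[HaplotypeBlock],
    m: GenotypeMatrix,
    p: BlockParams = BlockParams(),
) -> list[HaplotypeBlock]:
    """Merge overlapping per-sample blocks into named multi-carrier regions.

    Regions are unions of overlapping intervals on one chromosome.  A carrier
    is any matrix sample whose fraction of non-reference calls among its
    genotyped sites inside the region is at least ``carrier_frac`` — this
    recovers carriers whose own cluster narrowly missed detection and rejects
    samples whose private SNPs merely brush the region.  Regions with >= 2
    carriers are named cNrM by chromosome then start order; singleton regions
    are dropped (they remain in the per-sample output).
    """
    by_chrom: dict[str, list[HaplotypeBlock]] = {}
    for b in per_sample:
        by_chrom.setdefault(b.interval.chrom, []).append(b)
    named: list[HaplotypeBlock] = []
    for chrom in sorted(by_chrom):
        blocks = sorted(by_chrom[chrom], key=lambda b: b.interval.start)
        groups: list[list[HaplotypeBlock]] = []
        cur: list[HaplotypeBlock] = []
        cur_stop = -1
        for b in blocks:
            if cur and b.interval.start <= cur_stop:
                cur.append(b)
                cur_stop = max(cur_stop, b.interval.stop)
            else:
                if cur:
                    groups.append(cur)
                cur = [b]
                cur_stop = b.interval.stop
        if cur:
            groups.append(cur)
        rank = 0
        for group in groups:
            region = group[0].interval
            for b in group[1:]:
                region = region.union(b.interval)
            carriers = {}
            for sample in m.samples:
                genotyped, nonref, het = _carrier_stats(m, region, sample)
                if genotyped == 0:
                    continue
                if nonref / genotyped >= p.carrier_frac:
                    carriers[sample] = "HET" if nonref and het / nonref > 0.5 else "HOM"
            if len(carriers) < 2:
                continue
            rank += 1
            sub = {
                b.carriers.copy().pop(): b.interval
                for b in group
                if len(b.carriers) == 1
            }
            n_snps = int(m.region_mask(region).sum())
            named.append(
                HaplotypeBlock(
                    id=f"c{chrom}r{rank}",
                    interval=region,
                    carriers=set(carriers),
                    n_snps=n_snps,
                    carrier_zygosity=carriers,
                    carrier_intervals={s: iv for s, iv in sub.items() if s in carriers},
                )
            )
    return named


def consensus_calls(
    m: GenotypeMatrix, samples: set[str] | list[str], region: GenomicInterval
) -> np.ndarray:
    """Strict-majority consensus over a sample set, per site in the region.

    Ties among non-missing calls, and all-missing sites, yield MISSING.
    Returns an int8 vector aligned with ``m.subset_sites(m.region_mask(region))``.
    """
    if not samples:
        raise ValueError("empty sample set")
    idx = [m.sample_index(s) for s in sorted(samples)]
    calls = m.calls[np.ix_(m.region_mask(region).nonzero()[0], idx)]
    out = np.full(calls.shape[0], -1, dtype=np.int8)
    counts = np.stack([(calls == c).sum(axis=1) for c in (0, 1, 2)])
    top = counts.max(axis=0)
    winners = (counts == top).sum(axis=0)
    decided = (top > 0) & (winners == 1)
    out[decided] = counts[:, decided].argmax(axis=0)
    return out


def snp_block_fraction(m: GenotypeMatrix, regions: list[HaplotypeBlock]) -> float:
    """Fraction of matrix sites falling inside any named region."""
    if m.n_sites == 0:
        return 0.0
    mask = m.regions_mask([r.interval for r in regions])
    return float(mask.mean())


@dataclass
class BlockCoverage:
    """The multi-haplotype fraction under its two candidate definitions:
    bp of named regions over assayable genome bp, and genes overlapping
    named regions over all assayed genes."""

    bp_fraction: float | None = None
    gene_fraction: float | None = None
    n_block_genes: int | None = None
    n_genes: int | None = None


def multi_haplotype_fraction(
    regions: list[HaplotypeBlock],
    genome_bp: int | None = None,
    genes: list[GenomicInterval] | None = None,
) -> BlockCoverage:
    cov = BlockCoverage()
    intervals = [r.interval for r in regions]
    if genome_bp is not None:
        if genome_bp <= 0:
            raise ValueError("genome_bp must be positive")
        total = _union_bp(intervals)
        cov.bp_fraction = total / genome_bp
    if genes is not None:
        if not genes:
            raise ValueError("empty gene list")
        n_in = sum(1 for g in genes if any(g.overlaps(iv) for iv in intervals))
        cov.gene_fraction = n_in / len(genes)
        cov.n_block_genes = n_in
        cov.n_genes = len(genes)
    return cov


def _union_bp(intervals: list[GenomicInterval]) -> int:
    total = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda x: x.start)
        cur_start, cur_stop = ivs[0].start, ivs[0].stop
        for iv in ivs[1:]:
            if iv.start <= cur_stop + 1:
                cur_stop = max(cur_stop, iv.stop)
            else:
                total += cur_stop - cur_start + 1
                cur_start, cur_stop = iv.start, iv.stop
        total += cur_stop - cur_start + 1
    return total
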