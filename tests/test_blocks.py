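"""Haplotype-block detection, merging, consensus and coverage fractions."""

import numpy as np
import pytest

from b73prov import blocks as B
from b73prov.model import GenomicInterval
from _util import make_matrix


def _oracle_clusters(positions, max_gap, min_snps):
    """Independent gap-clustering scan over sorted positions."""
    clusters, cur = [], []
    for p in positions:
        if cur and p - cur[-1] > max_gap:
            clusters.append(cur)
            cur = []
        cur.append(p)
    if cur:
        clusters.append(cur)
    return [(c[0], c[-1], len(c)) for c in clusters if len(c) >= min_snps]


def test_detect_single_dense_block():
    pos = list(range(1_000_000, 1_000_000 + 50 * 20_000, 20_000))
    pos += [5_000_000, 9_000_000]  # scattered singletons
    calls = [[2]] * 50 + [[0], [0]]
    m = make_matrix(calls, positions=pos)
    out = B.detect_blocks(m, "s1", B.BlockParams())
    assert len(out) == 1
    assert (out[0].interval.start, out[0].interval.stop) == (pos[0], pos[49])
    assert out[0].n_snps == 50
    assert out[0].carrier_zygosity == {"s1": "HOM"}


def test_detect_no_nonreference_calls_gives_empty_list():
    m = make_matrix([[0], [0], [-1]])
    assert B.detect_blocks(m, "s1") == []


def test_detect_against_gap_clustering_oracle():
    rng = np.random.default_rng(5)
    p = B.BlockParams(min_snps=3, max_gap=500_000)
    pos = np.sort(rng.choice(50_000_000, 300, replace=False) + 1)
    nonref = rng.random(300) < 0.5
    calls = np.where(nonref, 2, 0)[:, None]
    m = make_matrix(calls, positions=list(pos))
    got = [(b.interval.start, b.interval.stop, b.n_snps)
           for b in B.detect_blocks(m, "s1", p)]
    want = _oracle_clusters(list(pos[nonref]), p.max_gap, p.min_snps)
    assert got == want


def test_two_clusters_separated_by_three_gaps():
    gap = B.BlockParams().max_gap
    left = [1 + i * 1000 for i in range(6)]
    right = [left[-1] + 3 * gap + i * 1000 for i in range(6)]
    m = make_matrix([[2]] * 12, positions=left + right)
    out = B.detect_blocks(m, "s1")
    assert [(b.interval.start, b.interval.stop) for b in out] == [
        (left[0], left[-1]), (right[0], right[-1])
    ]


def test_widening_max_gap_never_increases_block_count():
    """Merging is monotone once the size filter cannot intervene: every
    cluster already meets min_snps at the smallest gap (sites come in tight
    pairs), so larger gaps can only fuse clusters."""
    rng = np.random.default_rng(8)
    anchors = np.sort(rng.choice(80_000_000, 100, replace=False) + 1)
    pos = sorted(set(int(p) for a in anchors for p in (a, a + 1_000)))
    m = make_matrix([[2]] * len(pos), positions=pos)
    counts = [
        len(B.detect_blocks(m, "s1", B.BlockParams(min_snps=2, max_gap=g)))
        for g in (10_000, 100_000, 500_000, 2_000_000, 10_000_000)
    ]
    assert counts == sorted(counts, reverse=True)


def test_merge_identical_blocks_across_five_samples():
    calls = np.full((10, 6), 0, dtype=np.int8)
    calls[:, :5] = 2  # five carriers, one reference sample
    pos = [1_000_000 + i * 10_000 for i in range(10)]
    m = make_matrix(calls, positions=pos)
    per = []
    for s in m.samples:
        per.extend(B.detect_blocks(m, s))
    named = B.merge_blocks_across_samples(per, m)
    assert len(named) == 1
    assert named[0].id == "c1r1"
    assert named[0].carriers == {"s1", "s2", "s3", "s4", "s5"}
    assert named[0].n_snps == 10


def test_merge_shared_single_breakpoint_unions_intervals():
    # sample 1 carries sites 0..9, sample 2 carries 5..14: one shared edge
    calls = np.zeros((15, 3), dtype=np.int8)
    calls[:10, 0] = 2
    calls[5:, 1] = 2
    pos = [1_000_000 + i * 10_000 for i in range(15)]
    m = make_matrix(calls, positions=pos)
    per = []
    for s in m.samples:
        per.extend(B.detect_blocks(m, s))
    named = B.merge_blocks_across_samples(
        per, m, B.BlockParams(carrier_frac=0.6)
    )
    assert len(named) == 1
    region = named[0]
    assert (region.interval.start, region.interval.stop) == (pos[0], pos[14])
    assert region.carrier_intervals["s1"] == GenomicInterval("1", pos[0], pos[9])
    assert region.carrier_intervals["s2"] == GenomicInterval("1", pos[5], pos[14])


def test_singleton_block_excluded_from_named_regions():
    calls = np.zeros((8, 4), dtype=np.int8)
    calls[:, 0] = 2  # only one carrier
    m = make_matrix(calls, positions=[10_000 * (i + 1) for i in range(8)])
    per = []
    for s in m.samples:
        per.extend(B.detect_blocks(m, s))
    assert len(per) == 1  # per-sample output retains it
    assert B.merge_blocks_across_samples(per, m) == []


def test_heterozygous_carrier_is_flagged():
    calls = np.zeros((10, 3), dtype=np.int8)
    calls[:, 0] = 2
    calls[:, 1] = 1  # fully heterozygous carrier
    m = make_matrix(calls, positions=[10_000 * (i + 1) for i in range(10)])
    per = []
    for s in m.samples:
        per.extend(B.detect_blocks(m, s))
    named = B.merge_blocks_across_samples(per, m)
    assert named[0].carrier_zygosity == {"s1": "HOM", "s2": "HET"}


def test_consensus_rules():
    region = GenomicInterval("1", 1, 10_000)
    m = make_matrix(
        [[2, 2, 2, 2], [2, 2, 0, 0], [2, 2, 2, -1], [-1, -1, -1, -1], [1, 1, 0, -1]],
        positions=[100, 200, 300, 400, 500],
    )
    out = B.consensus_calls(m, {"s1", "s2", "s3", "s4"}, region)
    assert out.tolist() == [2, -1, 2, -1, 1]
    # single-sample consensus is the sample itself
    single = B.consensus_calls(m, {"s1"}, region)
    assert single.tolist() == m.calls[:, 0].tolist()
    with pytest.raises(ValueError):
        B.consensus_calls(m, set(), region)


def test_snp_block_fraction_bounds():
    m = make_matrix([[0, 2]] * 10, positions=[1000 * (i + 1) for i in range(10)])
    assert B.snp_block_fraction(m, []) == 0.0
    everything = B.HaplotypeBlock("x", GenomicInterval("1", 1, 20_000), {"s1", "s2"}, 10)
    assert B.snp_block_fraction(m, [everything]) == 1.0


def test_multi_haplotype_fraction_bp_and_genes():
    regions = [
        B.HaplotypeBlock("a", GenomicInterval("1", 1, 23_000_000), {"x", "y"}, 5)
    ]
    cov = B.multi_haplotype_fraction(regions, genome_bp=1_000_000_000)
    assert cov.bp_fraction == pytest.approx(0.023)
    genes = [GenomicInterval("1", 10_000_000, 10_005_000),
             GenomicInterval("1", 50_000_000, 50_005_000),
             GenomicInterval("2", 10_000_000, 10_005_000),
             GenomicInterval("1", 22_999_000, 23_100_000)]
    cov2 = B.multi_haplotype_fraction(regions, genes=genes)
    assert cov2.gene_fraction == pytest.approx(0.5)
    assert cov2.n_block_genes == 2
    assert B.multi_haplotype_fraction([], genome_bp=100).bp_fraction == 0.0
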