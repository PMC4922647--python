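"""FPKM computation, eligibility, expression-bias statistic, SNP-density r."""

import numpy as np
import pandas as pd
import pytest

from b73prov import expression as E
from b73prov.model import GenomicInterval
from _util import make_matrix


def _table(fpkm: np.ndarray, samples, chrom="1", starts=None, width=5_000):
    n_genes = fpkm.shape[0]
    if starts is None:
        starts = [1_000_000 * (i + 1) for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "stop": [s + width for s in starts],
            "exon_length": 1_000,
        }
    )
    df = pd.DataFrame(fpkm, index=genes["gene_id"], columns=samples)
    return E.ExpressionTable(genes, df)


def test_fpkm_formula_and_scaling():
    counts = pd.DataFrame({"s1": [100, 0], "s2": [100, 50]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1_000, "g2": 2_000})
    libs = pd.Series({"s1": 1_000_000, "s2": 2_000_000})
    t = E.compute_fpkm(counts, lengths, libs)
    assert t.fpkm.loc["g1", "s1"] == pytest.approx(100.0)
    assert t.fpkm.loc["g2", "s1"] == 0.0
    # doubling library size halves FPKM
    assert t.fpkm.loc["g1", "s2"] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        E.compute_fpkm(counts, pd.Series({"g1": 0, "g2": 10}), libs)


def test_eligibility_boundary():
    fpkm = np.array([[9.9, 9.9, 50.0, 50.0],
                     [10.0, 10.0, 10.0, 10.0],
                     [0.0, 0.0, 0.0, 0.0]])
    t = _table(fpkm, ["a1", "a2", "b1", "b2"])
    got = E.eligible_genes(t, ["a1", "a2"], ["b1", "b2"], min_fpkm=10.0)
    assert got == {"g2"}  # 9.9 excluded, exactly 10 included
    empty = _table(np.zeros((3, 4)), ["a1", "a2", "b1", "b2"])
    assert E.eligible_genes(empty, ["a1", "a2"], ["b1", "b2"]) == set()
    with pytest.raises(ValueError):
        E.eligible_genes(t, [], ["b1"])


def _bias_fixture(scale_in=1.0, n_genes=40, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(20, 200, n_genes)
    carrier = np.column_stack([base, base])
    ref = np.column_stack([base, base])
    carrier[: n_genes // 2] *= scale_in  # first half = in-block genes
    fpkm = np.hstack([carrier, ref])
    t = _table(fpkm, ["c1", "c2", "r1", "r2"])
    stop = int(t.genes.iloc[n_genes // 2 - 1]["stop"])
    regions = [GenomicInterval("1", 1, stop)]
    return t, regions


def test_bias_zero_when_groups_identical():
    t, regions = _bias_fixture(scale_in=1.0)
    out = E.expression_bias(t, regions, ["c1", "c2"], ["r1", "r2"])
    assert out.reduction == pytest.approx(0.0)
    assert not out.undefined


def test_bias_recovers_constructed_reduction():
    t, regions = _bias_fixture(scale_in=0.944)
    out = E.expression_bias(t, regions, ["c1", "c2"], ["r1", "r2"])
    assert out.reduction == pytest.approx(0.056, abs=1e-9)
    assert out.n_in == 20 and out.n_out == 20


def test_bias_invariant_to_common_rescaling():
    t, regions = _bias_fixture(scale_in=0.9)
    a = E.expression_bias(t, regions, ["c1", "c2"], ["r1", "r2"])
    scaled = E.ExpressionTable(t.genes, t.fpkm * 7.5)
    b = E.expression_bias(scaled, regions, ["c1", "c2"], ["r1", "r2"])
    assert a.reduction == pytest.approx(b.reduction)


def test_bias_undefined_without_in_block_genes():
    t, _ = _bias_fixture()
    far = [GenomicInterval("9", 1, 100)]
    out = E.expression_bias(t, far, ["c1", "c2"], ["r1", "r2"])
    assert out.undefined and np.isnan(out.reduction)


def test_density_correlation_extremes():
    # density exactly proportional to expression -> r = 1 in the stratum
    n = 30
    positions = []
    fpkm = np.zeros((n, 2))
    site_pos = []
    for i in range(n):
        start = 1_000_000 * (i + 1)
        positions.append(start)
        fpkm[i] = 10.0 * (i + 1)
        site_pos.extend(range(start, start + i + 1))  # i+1 SNPs in gene i
    t = _table(fpkm, ["s1", "s2"], starts=positions)
    m = make_matrix([[0, 2]] * len(site_pos), positions=site_pos)
    out = E.snp_density_correlation(t, m, regions=[])
    assert out.r_out == pytest.approx(1.0)
    assert out.undefined_in  # no genes inside regions

    # constant density -> zero variance -> flagged undefined
    m2 = make_matrix([[0, 2]] * n, positions=positions)
    flat = E.snp_density_correlation(t, m2, regions=[])
    assert flat.undefined_out


def test_density_correlation_null_is_small():
    rng = np.random.default_rng(12)
    n = 1000
    starts = [10_000 * (i + 1) for i in range(n)]
    fpkm = rng.lognormal(3, 1, size=(n, 2))
    t = _table(fpkm, ["s1", "s2"], starts=starts, width=1_000)
    site_pos = []
    for i in range(n):
        for _ in range(rng.integers(0, 5)):
            site_pos.append(starts[i] + int(rng.integers(0, 1000)))
    site_pos = sorted(set(site_pos))
    m = make_matrix([[0, 2]] * len(site_pos), positions=site_pos)
    out = E.snp_density_correlation(t, m, regions=[])
    assert abs(out.r_out) < 0.1
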