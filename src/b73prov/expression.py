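"""Expression consequences of introgressed haplotype blocks.

The bias statistic formalizes an in-block vs out-of-block comparison: for
every eligible gene the ratio of carrier-group median FPKM to reference-group
median FPKM is taken, and the median of those ratios over in-block genes is
normalized by the same median over out-of-block genes.  ``reduction`` is one
minus that normalized ratio, so a value of 0.056 means genes inside
introgressed regions are expressed 5.6% lower in carriers than the genome-wide
behaviour of the two groups predicts.  Normalizing by the out-of-block
stratum cancels global differences between the two groups of datasets
(library composition, lab effects), isolating the block-linked component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import GenotypeMatrix
from .model import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

GENE_META_COLUMNS = ["gene_id", "chrom", "start", "stop", "exon_length"]


class ExpressionTable:
    """Genes x samples FPKM values plus gene coordinates and exon lengths.

    ``genes`` has columns gene_id, chrom, start, stop, exon_length (1-based
    inclusive coordinates); ``fpkm`` is a DataFrame indexed by gene_id with
    one column per sample.  ``gene_models`` optionally carries full exon
    structures for exon-resolution interval tests.
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        fpkm: pd.DataFrame,
        gene_models: dict[str, GeneModel] | None = None,
    ) -> None:
        genes = genes.reset_index(drop=True)
        missing = [c for c in GENE_META_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if list(fpkm.index) != list(genes["gene_id"]):
            raise ValueError("fpkm index must equal the gene_id column")
        if (fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if (genes["exon_length"] <= 0).any():
            raise ValueError("exon lengths must be positive")
        self.genes = genes
        self.fpkm = fpkm
        self.gene_models = gene_models or {}

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)

    def gene_interval(self, gene_id: str) -> GenomicInterval:
        row = self.genes.loc[self.genes["gene_id"] == gene_id].iloc[0]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["stop"]))

    def in_region_genes(self, regions: list[GenomicInterval]) -> set[str]:
        """Genes with any exon overlap with any region (gene-span overlap
        when no exon structure is attached)."""
        out = set()
        for row in self.genes.itertuples(index=False):
            model = self.gene_models.get(row.gene_id)
            ivs = (
                model.exons
                if model is not None and model.exons
                else [GenomicInterval(row.chrom, int(row.start), int(row.stop))]
            )
            if any(iv.overlaps(r) for iv in ivs for r in regions):
                out.add(row.gene_id)
        return out


def compute_fpkm(
    read_counts: pd.DataFrame,
    exon_lengths: pd.Series,
    library_sizes: pd.Series,
    genes: pd.DataFrame | None = None,
) -> ExpressionTable:
    """FPKM = counts * 1e9 / (library size * exon length in bp)."""
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if (exon_lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    lengths = exon_lengths.reindex(read_counts.index)
    if lengths.isna().any():
        raise ValueError("exon length missing for some genes")
    sizes = library_sizes.reindex(read_counts.columns)
    if sizes.isna().any():
        raise ValueError("library size missing for some samples")
    fpkm = read_counts.mul(1e9).div(sizes, axis=1).div(lengths, axis=0)
    if genes is None:
        genes = pd.DataFrame(
            {
                "gene_id": read_counts.index,
                "chrom": "NA",
                "start": 1,
                "stop": 1,
                "exon_length": lengths.to_numpy(),
            }
        )
    return ExpressionTable(genes, fpkm)


def eligible_genes(
    t: ExpressionTable,
    group_a: list[str],
    group_b: list[str],
    min_fpkm: float = 10.0,
) -> set[str]:
    """Genes whose mean FPKM is at least ``min_fpkm`` in both groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    mean_a = t.fpkm[list(group_a)].mean(axis=1)
    mean_b = t.fpkm[list(group_b)].mean(axis=1)
    keep = (mean_a >= min_fpkm) & (mean_b >= min_fpkm)
    return set(t.fpkm.index[keep])


@dataclass
class BiasResult:
    n_in: int
    n_out: int
    median_ratio_in: float
    median_ratio_out: float
    reduction: float
    undefined: bool = False


def expression_bias(
    t: ExpressionTable,
    regions: list[GenomicInterval],
    group_carrier: list[str],
    group_ref: list[str],
    min_fpkm: float = 10.0,
) -> BiasResult:
    """Carrier-vs-reference expression comparison stratified by block status.

    Invariant to rescaling all samples' FPKM by a common constant, and zero
    exactly when both strata have identical per-gene median ratios.
    """
    eligible = eligible_genes(t, group_carrier, group_ref, min_fpkm)
    in_genes = t.in_region_genes(regions) & eligible
    out_genes = eligible - in_genes
    med_c = t.fpkm[list(group_carrier)].median(axis=1)
    med_r = t.fpkm[list(group_ref)].median(axis=1)
    ok = med_r > 0
    dropped = [g for g in eligible if not ok.get(g, False)]
    if dropped:
        logger.info("%d eligible genes dropped (zero reference median)", len(dropped))
    ratios = (med_c[ok] / med_r[ok]).dropna()
    r_in = ratios[ratios.index.isin(in_genes)]
    r_out = ratios[ratios.index.isin(out_genes)]
    if len(r_in) == 0 or len(r_out) == 0:
        return BiasResult(len(r_in), len(r_out), float("nan"), float("nan"),
                          float("nan"), undefined=True)
    m_in = float(r_in.median())
    m_out = float(r_out.median())
    reduction = 1.0 - m_in / m_out if m_out > 0 else float("nan")
    return BiasResult(len(r_in), len(r_out), m_in, m_out, reduction,
                      undefined=not np.isfinite(reduction))


@dataclass
class DensityCorrelation:
    r_out: float
    r_in: float
    n_out: int
    n_in: int
    undefined_out: bool = False
    undefined_in: bool = False


def snp_density_correlation(
    t: ExpressionTable,
    m: GenotypeMatrix,
    regions: list[GenomicInterval],
    eligible: set[str] | None = None,
) -> DensityCorrelation:
    """Pearson r between per-gene exonic SNP density (segregating SNPs per
    1000 exon bases) and median FPKM across all datasets, computed separately
    for genes outside and inside block regions.

    Strata with fewer than 3 genes or zero variance are flagged undefined
    (r = nan).
    """
    in_genes = t.in_region_genes(regions)
    med = t.fpkm.median(axis=1)
    site_pos = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in m.sites.groupby("chrom", sort=False)
    }

    def _count_snps(chrom: str, ivs: list[GenomicInterval]) -> int:
        pos = site_pos.get(chrom)
        if pos is None:
            return 0
        return int(
            sum(
                np.searchsorted(pos, iv.stop, "right")
                - np.searchsorted(pos, iv.start, "left")
                for iv in ivs
            )
        )

    rows = {"in": ([], []), "out": ([], [])}
    for row in t.genes.itertuples(index=False):
        if eligible is not None and row.gene_id not in eligible:
            continue
        model = t.gene_models.get(row.gene_id)
        ivs = (
            model.exons
            if model is not None and model.exons
            else [GenomicInterval(row.chrom, int(row.start), int(row.stop))]
        )
        density = 1000.0 * _count_snps(row.chrom, ivs) / row.exon_length
        bucket = "in" if row.gene_id in in_genes else "out"
        rows[bucket][0].append(density)
        rows[bucket][1].append(float(med[row.gene_id]))

    def _corr(xs: list[float], ys: list[float]) -> tuple[float, bool]:
        if len(xs) < 3:
            return float("nan"), True
        x = np.asarray(xs)
        y = np.asarray(ys)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan"), True
        return float(stats.pearsonr(x, y).statistic), False

    r_out, und_out = _corr(*rows["out"])
    r_in, und_in = _corr(*rows["in"])
    return DensityCorrelation(
        r_out=r_out, r_in=r_in,
        n_out=len(rows["out"][0]), n_in=len(rows["in"][0]),
        undefined_out=und_out, undefined_in=und_in,
    )
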