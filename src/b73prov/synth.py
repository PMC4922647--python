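"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a cohort of nominally identical inbred samples
sequenced by RNA-seq in independent labs: a lineage tree of clades and
subclades, megabase-scale introgressed donor haplotype blocks shared by whole
clades, a sparse background of lineage-private SNPs, residual
heterozygosity, overdispersed exon-limited read depth with miscall noise, a
donor haplotype panel in which each block's true donor is present, and a
per-gene FPKM table where genes inside a block are expressed a fixed factor
lower in carrier samples.

Defaults mirror the study conditions the pipeline is meant to recover:
27 samples in three clades (one with three subclades), 13,360 segregating
SNPs of which 55.3% sit inside seven blocks on chromosomes 2, 4, 5 and 6
with the block geometry of the real survey, a 103-haplotype donor panel, and
a 5.6% multiplicative expression reduction inside carried blocks.

Truth objects (tree, blocks, genotypes, donor assignments) are returned
alongside the observations for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .blocks import HaplotypeBlock
from .expression import ExpressionTable
from .genotyping import GenotypeMatrix
from .model import AlleleDepthTable, GeneModel, GenomicInterval, SITE_COLUMNS
from .origin import PanelMatrix

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class Clade:
    """A named lineage; leaves carry samples, internal clades carry children."""

    name: str
    n_samples: int = 0
    children: list["Clade"] = field(default_factory=list)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_clades(self) -> list["Clade"]:
        return [c for c in self.walk() if not c.children]

    def find(self, name: str) -> "Clade | None":
        for c in self.walk():
            if c.name == name:
                return c
        return None


@dataclass(frozen=True)
class Introgression:
    clade: str
    interval: GenomicInterval
    donor: int


def default_lineage() -> Clade:
    """Three major clades, one with three subclades; 27 samples total."""
    return Clade("root", children=[
        Clade("USA_South", children=[
            Clade("USDA", 7),
            Clade("Iowa_State", 6),
            Clade("UC_Berkeley", 6),
        ]),
        Clade("North_group", children=[
            Clade("USA_North", 5),
            Clade("China", 3),
        ]),
    ])


def default_introgressions() -> list[Introgression]:
    """Seven blocks with the survey's geometry (kb coordinates x 1000)."""
    return [
        Introgression("China", GenomicInterval("2", 40_000_000, 44_300_000), 0),
        Introgression("North_group", GenomicInterval("2", 212_450_000, 224_250_000), 1),
        Introgression("China", GenomicInterval("4", 169_650_000, 191_550_000), 2),
        Introgression("North_group", GenomicInterval("5", 201_200_000, 203_000_000), 3),
        Introgression("North_group", GenomicInterval("5", 209_732_000, 211_540_000), 4),
        Introgression("China", GenomicInterval("6", 120_000, 8_800_000), 5),
        Introgression("China", GenomicInterval("6", 20_900_000, 24_670_000), 6),
    ]


@dataclass
class SimConfig:
    n_chromosomes: int = 10
    chrom_length: int = 240_000_000
    n_sites: int = 13_360
    n_genes: int = 25_644
    lineage_spec: Clade = field(default_factory=default_lineage)
    introgressions: list[Introgression] = field(default_factory=default_introgressions)
    n_donors: int = 103
    donor_divergence: float = 0.10
    block_snp_fraction: float = 0.553
    internal_branch_weight: float = 0.3
    residual_het_rate: float = 0.002
    depth_mean: float = 20.0
    depth_dispersion: float = 2.0
    error_rate: float = 0.01
    expression_log_mean: float = math.log(60.0)
    expression_log_sd: float = 1.0
    expression_noise_sd: float = 0.2
    expression_reduction: float = 0.056
    seed: int = 0

    def validate(self) -> None:
        for name in ("donor_divergence", "block_snp_fraction", "residual_het_rate",
                     "error_rate", "expression_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        clade_names = {c.name for c in self.lineage_spec.walk()}
        for intro in self.introgressions:
            if intro.clade not in clade_names:
                raise ValueError(f"introgression references unknown clade {intro.clade!r}")
            if not 0 <= intro.donor < self.n_donors:
                raise ValueError(f"introgression references unknown donor {intro.donor}")
            iv = intro.interval
            if int(iv.chrom) > self.n_chromosomes or iv.stop > self.chrom_length:
                raise ValueError(f"introgression {iv} outside chromosome bounds")
        if sum(c.n_samples for c in self.lineage_spec.leaf_clades()) < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class TruthSet:
    true_tree: dendropy.Tree
    true_blocks: list[HaplotypeBlock]
    true_genotypes: GenotypeMatrix
    donor_assignments: dict[str, str]
    clade_samples: dict[str, list[str]]
    site_block: np.ndarray  # block index per site, -1 = background
    block_genes: dict[str, set[str]]


@dataclass
class SimResult:
    config: SimConfig
    depths: AlleleDepthTable
    expression: ExpressionTable
    panel: PanelMatrix
    truth: TruthSet
    genes: list[GeneModel]
    cds_sequences: dict[str, str]

    def cds_sequence(self, gene_id: str) -> str:
        if gene_id not in self.cds_sequences:
            index = int(gene_id.split("g")[-1]) - 1
            self.cds_sequences[gene_id] = _gene_cds(self.config.seed, index,
                                                   self._exon_length(gene_id))
        return self.cds_sequences[gene_id]

    def _exon_length(self, gene_id: str) -> int:
        row = self.expression.genes.loc[self.expression.genes["gene_id"] == gene_id]
        return int(row["exon_length"].iloc[0])


def expected_donor_fraction(n_backcrosses: int) -> float:
    """Expected donor-parent genome contribution after n backcrosses to the
    recurrent parent: (1/2)^(n+1)."""
    if n_backcrosses < 0:
        raise ValueError("n_backcrosses must be >= 0")
    return 0.5 ** (n_backcrosses + 1)


def _gene_cds(seed: int, gene_index: int, exon_length: int) -> str:
    """Deterministic CDS for one gene: ATG, sense codons, one stop."""
    assert exon_length % 3 == 0 and exon_length >= 9
    rng = np.random.default_rng([seed % (2**31), 7_777, gene_index])
    n_mid = exon_length // 3 - 2
    mid = rng.choice(len(_SENSE_CODONS), n_mid)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in mid) + stop


def _clade_tree(spec: Clade, samples_of: dict[str, list[str]]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(clade: Clade, node: dendropy.Node) -> None:
        node.label = clade.name
        if clade.children:
            for child in clade.children:
                cn = dendropy.Node()
                cn.edge.length = 0.3
                node.add_child(cn)
                build(child, cn)
        else:
            for s in samples_of[clade.name]:
                leaf = dendropy.Node(taxon=tns.require_taxon(label=s))
                leaf.edge.length = 1.0
                node.add_child(leaf)

    build(spec, tree.seed_node)
    tree.is_rooted = True
    return tree


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic dataset plus its truth set.

    Deterministic given ``config`` (all randomness flows from ``config.seed``
    through named substreams, one per generation stage).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_genes, rng_sites, rng_geno, rng_depth, rng_panel, rng_expr = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    # ---- lineage and samples ---------------------------------------------
    spec = config.lineage_spec
    samples_of: dict[str, list[str]] = {}
    samples: list[str] = []
    for clade in spec.leaf_clades():
        names = [f"{clade.name}_{i + 1:02d}" for i in range(clade.n_samples)]
        samples_of[clade.name] = names
        samples.extend(names)
    n_samples = len(samples)
    sample_index = {s: j for j, s in enumerate(samples)}

    def descendants(clade_name: str) -> list[str]:
        clade = spec.find(clade_name)
        out: list[str] = []
        for c in clade.walk():
            out.extend(samples_of.get(c.name, []))
        return out

    clade_samples = {
        c.name: descendants(c.name) for c in spec.walk() if c.name != "root"
    }

    # ---- gene models ------------------------------------------------------
    n_genes = config.n_genes
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    gene_chrom_i = rng_genes.integers(0, config.n_chromosomes, n_genes)
    e1 = rng_genes.integers(300, 900, n_genes)
    e2 = rng_genes.integers(300, 900, n_genes)
    total = e1 + e2
    e2 = e2 + (3 - total % 3) % 3  # CDS length multiple of 3
    intron = rng_genes.integers(100, 3000, n_genes)
    span = e1 + intron + e2
    start = rng_genes.integers(1, config.chrom_length - span.max(), n_genes)
    strand = np.where(rng_genes.random(n_genes) < 0.5, "+", "-")
    order = np.lexsort((start, gene_chrom_i))
    genes: list[GeneModel] = []
    for rank, gi in enumerate(order):
        chrom = chroms[gene_chrom_i[gi]]
        s = int(start[gi])
        ex1 = GenomicInterval(chrom, s, s + int(e1[gi]) - 1)
        s2 = ex1.stop + int(intron[gi]) + 1
        ex2 = GenomicInterval(chrom, s2, s2 + int(e2[gi]) - 1)
        genes.append(
            GeneModel(
                gene_id=f"g{rank + 1:05d}",
                interval=GenomicInterval(chrom, s, ex2.stop),
                strand=str(strand[gi]),
                exons=[ex1, ex2],
            )
        )

    # exon bookkeeping per chromosome for site placement
    exon_rows = []
    for g in genes:
        for ex in g.exons:
            exon_rows.append((ex.chrom, ex.start, ex.stop, g.gene_id))
    exon_df = pd.DataFrame(exon_rows, columns=["chrom", "start", "stop", "gene_id"])

    # ---- site placement (exonic, as expected for RNA-seq detection) -------
    intro_list = list(config.introgressions)
    n_block_total = int(round(config.n_sites * config.block_snp_fraction))
    lengths = np.array([iv.interval.length for iv in intro_list], dtype=float)
    if intro_list:
        alloc = np.floor(n_block_total * lengths / lengths.sum()).astype(int)
        for i in np.argsort(-(n_block_total * lengths / lengths.sum() - alloc)):
            if alloc.sum() >= n_block_total:
                break
            alloc[i] += 1
    else:
        alloc = np.array([], dtype=int)
    n_bg = config.n_sites - int(alloc.sum())

    taken: set[tuple[str, int]] = set()

    def sample_exonic(region: GenomicInterval | None, k: int, chrom: str | None,
                      rng: np.random.Generator) -> list[tuple[str, int, str]]:
        """k unique exonic positions (chrom, pos, gene_id), optionally
        restricted to a region or chromosome."""
        if region is not None:
            sub = exon_df[
                (exon_df["chrom"] == region.chrom)
                & (exon_df["stop"] >= region.start)
                & (exon_df["start"] <= region.stop)
            ].copy()
            sub["start"] = sub["start"].clip(lower=region.start)
            sub["stop"] = sub["stop"].clip(upper=region.stop)
        elif chrom is not None:
            sub = exon_df[exon_df["chrom"] == chrom]
        else:
            sub = exon_df
        if sub.empty:
            raise ValueError(f"no exonic sequence available in {region}")
        lens = (sub["stop"] - sub["start"] + 1).to_numpy()
        cum = np.cumsum(lens)
        out: list[tuple[str, int, str]] = []
        attempts = 0
        while len(out) < k:
            attempts += 1
            if attempts > 200:
                raise ValueError(f"cannot place {k} unique exonic sites in {region}")
            offs = rng.integers(0, cum[-1], k - len(out))
            rows = np.searchsorted(cum, offs, side="right")
            for off, r in zip(offs, rows):
                prev = cum[r - 1] if r else 0
                pos = int(sub.iloc[r]["start"] + (off - prev))
                key = (str(sub.iloc[r]["chrom"]), pos)
                if key in taken:
                    continue
                taken.add(key)
                out.append((key[0], pos, str(sub.iloc[r]["gene_id"])))
                if len(out) == k:
                    break
        return out

    site_records: list[tuple[str, int, str, int]] = []  # chrom, pos, gene, block idx
    for bi, (intro, k) in enumerate(zip(intro_list, alloc)):
        for chrom, pos, gid in sample_exonic(intro.interval, int(k), None, rng_sites):
            site_records.append((chrom, pos, gid, bi))

    # background sites: private to one lineage edge, weighted toward terminal
    # branches (long inbred propagation) over internal ones (few generations)
    lineage_nodes = [c.name for c in spec.walk() if c.name != "root"]
    lineage_nodes += samples
    weights = np.array(
        [config.internal_branch_weight] * (len(lineage_nodes) - n_samples)
        + [1.0] * n_samples
    )
    weights = weights / weights.sum()
    bg_lineages = rng_sites.choice(len(lineage_nodes), n_bg, p=weights)
    bg_positions = sample_exonic(None, n_bg, None, rng_sites)
    for (chrom, pos, gid), li in zip(bg_positions, bg_lineages):
        site_records.append((chrom, pos, gid, -1000 - int(li)))

    sites_raw = pd.DataFrame(site_records, columns=["chrom", "pos", "gene_id", "tag"])
    sites_raw = sites_raw.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    n_sites = len(sites_raw)
    site_block = np.where(sites_raw["tag"] >= 0, sites_raw["tag"], -1)

    # ---- truth genotypes --------------------------------------------------
    G = np.zeros((n_sites, n_samples), dtype=np.int8)
    carriers_of_block: list[list[str]] = [descendants(i.clade) for i in intro_list]
    for i, tag in enumerate(sites_raw["tag"]):
        if tag >= 0:
            cols = [sample_index[s] for s in carriers_of_block[tag]]
        else:
            node = lineage_nodes[-1000 - int(tag)]
            members = [node] if node in sample_index else descendants(node)
            cols = [sample_index[s] for s in members]
        G[i, cols] = 2
    het_mask = rng_geno.random(G.shape) < config.residual_het_rate
    G[het_mask] = 1

    # ---- alleles consistent with gene sequences ---------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    cds_cache: dict[str, str] = {}
    refs, alts = [], []
    for row in sites_raw.itertuples(index=False):
        g = gene_by_id[row.gene_id]
        if g.gene_id not in cds_cache:
            cds_cache[g.gene_id] = _gene_cds(config.seed, int(g.gene_id[1:]) - 1,
                                             g.exon_length)
        tpos = g.transcript_position(int(row.pos))
        base = cds_cache[g.gene_id][tpos]
        ref = base if g.strand == "+" else base.translate(_COMPLEMENT)
        alt_choices = [b for b in "ACGT" if b != ref]
        alt = alt_choices[rng_geno.integers(0, 3)]
        refs.append(ref)
        alts.append(alt)

    sites = pd.DataFrame(
        {"chrom": sites_raw["chrom"], "pos": sites_raw["pos"],
         "ref": refs, "alt": alts},
        columns=SITE_COLUMNS,
    )

    # ---- expression (needed before depths: coverage tracks expression) ----
    base = rng_expr.lognormal(config.expression_log_mean, config.expression_log_sd,
                              n_genes)
    noise = rng_expr.lognormal(0.0, config.expression_noise_sd, (n_genes, n_samples))
    fpkm = base[:, None] * noise
    block_genes: dict[str, set[str]] = {}
    block_names = _block_names(intro_list)
    for bi, intro in enumerate(intro_list):
        hit = {
            g.gene_id for g in genes
            if any(ex.overlaps(intro.interval) for ex in g.exons)
        }
        block_genes[block_names[bi]] = hit
        cols = [sample_index[s] for s in carriers_of_block[bi]]
        rows = [int(gid[1:]) - 1 for gid in hit]
        fpkm[np.ix_(rows, cols)] *= 1.0 - config.expression_reduction
    genes_meta = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "stop": [g.interval.stop for g in genes],
            "exon_length": [g.exon_length for g in genes],
        }
    )
    fpkm_df = pd.DataFrame(fpkm, index=genes_meta["gene_id"], columns=samples)
    expression = ExpressionTable(genes_meta, fpkm_df, gene_models=gene_by_id)

    # ---- read depths ------------------------------------------------------
    gene_row = {g.gene_id: i for i, g in enumerate(genes)}
    site_gene_i = np.array([gene_row[gid] for gid in sites_raw["gene_id"]])
    factor = np.clip(base[site_gene_i] / np.median(base), 0.05, 20.0)
    mean = config.depth_mean * factor
    k = config.depth_dispersion
    depth = rng_depth.negative_binomial(k, k / (k + mean[:, None]),
                                        (n_sites, n_samples))
    e = config.error_rate
    pvals = np.empty((n_sites, n_samples, 3))
    pvals[G == 0] = (1.0 - e, e / 2.0, e / 2.0)
    pvals[G == 1] = ((1.0 - e) / 2.0, (1.0 - e) / 2.0, e)
    pvals[G == 2] = (e / 2.0, 1.0 - e, e / 2.0)
    reads = rng_depth.multinomial(depth, pvals)
    depths = AlleleDepthTable(sites, samples, reads[..., 0].astype(np.int64),
                              reads[..., 1].astype(np.int64),
                              reads[..., 2].astype(np.int64))

    # ---- donor panel ------------------------------------------------------
    panel_names = [f"H{i + 1:03d}" for i in range(config.n_donors)]
    pcalls = np.where(
        rng_panel.random((n_sites, config.n_donors)) < config.donor_divergence, 2, 0
    ).astype(np.int8)
    for bi, intro in enumerate(intro_list):
        pcalls[site_block == bi, intro.donor] = 2
    panel = PanelMatrix(sites, panel_names, pcalls)

    # ---- truth ------------------------------------------------------------
    true_blocks = []
    donor_assignments = {}
    for bi, intro in enumerate(intro_list):
        carriers = set(carriers_of_block[bi])
        true_blocks.append(
            HaplotypeBlock(
                id=block_names[bi],
                interval=intro.interval,
                carriers=carriers,
                n_snps=int((site_block == bi).sum()),
                carrier_zygosity={s: "HOM" for s in carriers},
            )
        )
        donor_assignments[block_names[bi]] = panel_names[intro.donor]
    truth = TruthSet(
        true_tree=_clade_tree(spec, samples_of),
        true_blocks=true_blocks,
        true_genotypes=GenotypeMatrix(sites, samples, G),
        donor_assignments=donor_assignments,
        clade_samples=clade_samples,
        site_block=site_block,
        block_genes=block_genes,
    )
    cds_sequences = {gid: cds_cache[gid] for gid in set(sites_raw["gene_id"])}
    return SimResult(config, depths, expression, panel, truth, genes, cds_sequences)


def write_outputs(result: SimResult, outdir, provenance: str | None = None) -> None:
    """Write observations and truth files for a simulation.

    Layout: depths.tsv, depths.vcf, expression.tsv, panel.tsv, genes.gff3,
    cds.fa (genes containing SNPs only), truth/{tree.nwk, blocks.bed,
    genotypes.tsv, donors.tsv}.
    """
    import os

    from . import io as bio

    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    bio.write_allele_depths_tsv(result.depths, os.path.join(outdir, "depths.tsv"),
                                header_comment=provenance)
    bio.write_allele_depths_vcf(result.depths, os.path.join(outdir, "depths.vcf"),
                                header_comment=provenance)
    bio.write_expression_tsv(result.expression, os.path.join(outdir, "expression.tsv"),
                             header_comment=provenance)
    bio.write_genotype_matrix(result.panel, os.path.join(outdir, "panel.tsv"),
                              header_comment=provenance)
    bio.write_gff3_genes(result.genes, os.path.join(outdir, "genes.gff3"),
                         header_comment=provenance)
    bio.write_fasta(
        {gid: result.cds_sequences[gid] for gid in sorted(result.cds_sequences)},
        os.path.join(outdir, "cds.fa"),
    )
    bio.write_newick(result.truth.true_tree, os.path.join(outdir, "truth", "tree.nwk"),
                     header_comment=provenance)
    bio.write_blocks_bed(result.truth.true_blocks,
                         os.path.join(outdir, "truth", "blocks.bed"),
                         header_comment=provenance)
    bio.write_genotype_matrix(result.truth.true_genotypes,
                              os.path.join(outdir, "truth", "genotypes.tsv"),
                              header_comment=provenance)
    with open(os.path.join(outdir, "truth", "donors.tsv"), "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("block_id\tdonor\n")
        for bid in sorted(result.truth.donor_assignments):
            fh.write(f"{bid}\t{result.truth.donor_assignments[bid]}\n")


def _block_names(intro_list: list[Introgression]) -> list[str]:
    """cNrM labels in chromosome order then start order."""
    order = sorted(
        range(len(intro_list)),
        key=lambda i: (intro_list[i].interval.chrom, intro_list[i].interval.start),
    )
    names = [""] * len(intro_list)
    rank: dict[str, int] = {}
    for i in order:
        chrom = intro_list[i].interval.chrom
        rank[chrom] = rank.get(chrom, 0) + 1
        names[i] = f"c{chrom}r{rank[chrom]}"
    return names
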