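"""Readers and writers for every external format the pipeline touches.

All interval I/O converts at a single point between the internal 1-based
inclusive convention and BED's 0-based half-open one.  TSV files use a header
row, tab separation and '.' for missing values; lines starting with '#' are
treated as provenance/comment lines by every reader here.
"""

from __future__ import annotations

import os
from typing import Iterable, TYPE_CHECKING

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlleleDepthTable, GeneModel, GenomicInterval, SITE_COLUMNS
from .genotyping import GenotypeMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .blocks import HaplotypeBlock

DEPTH_TSV_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele",
    "sample", "ref_count", "alt_count", "other_count",
]


# ---------------------------------------------------------------------------
# allele depths

def read_allele_depths(path: str | os.PathLike, format: str | None = None) -> AlleleDepthTable:
    """Read per-site per-sample allele depths from VCF (AD field) or TSV.

    Multi-allelic VCF records are reduced to biallelic form: the alternate
    allele with the highest total depth across samples is kept and all other
    non-reference reads are pooled into ``other_count``.
    """
    path = os.fspath(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_depths_vcf(path)
    if format == "tsv":
        return _read_depths_tsv(path)
    raise ValueError(f"unknown allele-depth format {format!r}")


def _read_depths_vcf(path: str) -> AlleleDepthTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    seen: set[tuple[str, int]] = set()
    sites = []
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"duplicate site {var.CHROM}:{var.POS} in {path}")
        seen.add(key)
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks per-sample AD")
        ad = np.asarray(ad, dtype=np.int64)
        if ad.ndim == 1:
            ad = ad[:, None]
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes '.' as negative
        n_alt = len(var.ALT)
        if n_alt == 0:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no ALT allele")
        alt_depths = ad[:, 1:1 + n_alt]
        best = int(np.argmax(alt_depths.sum(axis=0)))
        ref_c = ad[:, 0]
        alt_c = alt_depths[:, best]
        other_c = ad[:, 1:].sum(axis=1) - alt_c
        sites.append((var.CHROM, var.POS, var.REF, var.ALT[best]))
        rows.append((ref_c, alt_c, other_c))
    if not sites:
        empty = pd.DataFrame(columns=SITE_COLUMNS)
        z = np.zeros((0, len(samples)), dtype=np.int64)
        return AlleleDepthTable(empty, samples, z, z.copy(), z.copy())
    order = sorted(range(len(sites)), key=lambda i: (sites[i][0], sites[i][1]))
    sites_df = pd.DataFrame([sites[i] for i in order], columns=SITE_COLUMNS)
    ref = np.stack([rows[i][0] for i in order])
    alt = np.stack([rows[i][1] for i in order])
    other = np.stack([rows[i][2] for i in order])
    return AlleleDepthTable(sites_df, samples, ref, alt, other)


def _read_depths_tsv(path: str) -> AlleleDepthTable:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty or header-less TSV") from None
    missing = [c for c in DEPTH_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = [
        (r.chrom, int(r.pos), r.ref_allele, r.alt_allele, r.sample,
         int(r.ref_count), int(r.alt_count), int(r.other_count))
        for r in df.itertuples(index=False)
    ]
    return AlleleDepthTable.from_records(records)


def write_allele_depths_tsv(
    depths: AlleleDepthTable, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(DEPTH_TSV_COLUMNS) + "\n")
        for i in range(depths.n_sites):
            chrom, pos, ref, alt = depths.sites.iloc[i][:4]
            for j, sample in enumerate(depths.samples):
                fh.write(
                    f"{chrom}\t{pos}\t{ref}\t{alt}\t{sample}\t"
                    f"{depths.ref[i, j]}\t{depths.alt[i, j]}\t{depths.other[i, j]}\n"
                )


def write_allele_depths_vcf(
    depths: AlleleDepthTable, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    """Write a minimal VCF 4.2 with per-sample AD (ref,alt depths; 'other'
    reads appear as a third depth on a symbolic non-ref allele when present)."""
    chroms = list(dict.fromkeys(depths.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##source={header_comment}\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(depths.samples) + "\n")
        any_other = depths.other.any(axis=1)
        for i in range(depths.n_sites):
            chrom, pos, ref, alt = depths.sites.iloc[i][:4]
            if any_other[i]:
                alt_field = f"{alt},<OTHER>"
                cells = [
                    f"{depths.ref[i, j]},{depths.alt[i, j]},{depths.other[i, j]}"
                    for j in range(depths.n_samples)
                ]
            else:
                alt_field = alt
                cells = [
                    f"{depths.ref[i, j]},{depths.alt[i, j]}"
                    for j in range(depths.n_samples)
                ]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt_field}\t.\t.\t.\tAD\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# haplotype blocks (BED)

def write_blocks_bed(
    blocks: Iterable["HaplotypeBlock"], path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    """BED5 + a sixth comma-joined carriers column (chrom, 0-based start,
    half-open end, block id, carrier count, carriers)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for b in blocks:
            chrom, start0, end = b.interval.to_bed_fields()
            carriers = ",".join(sorted(b.carriers))
            fh.write(f"{chrom}\t{start0}\t{end}\t{b.id}\t{len(b.carriers)}\t{carriers}\n")


def read_blocks_bed(path: str | os.PathLike) -> list["HaplotypeBlock"]:
    from .blocks import HaplotypeBlock

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 BED columns")
            chrom, start0, end, name, _score = parts[:5]
            carriers = set(parts[5].split(",")) if len(parts) > 5 and parts[5] else set()
            out.append(
                HaplotypeBlock(
                    id=name,
                    interval=GenomicInterval.from_bed_fields(chrom, int(start0), int(end)),
                    carriers=carriers,
                    n_snps=0,
                    carrier_zygosity={},
                )
            )
    return out


# ---------------------------------------------------------------------------
# trees (Newick)

def write_newick(
    tree: dendropy.Tree, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 labelled leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    text = tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"[{header_comment}]\n")
        fh.write(text)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=os.fspath(path), schema="newick")


# ---------------------------------------------------------------------------
# genotype / panel matrices (TSV; 0=HOM_REF, 1=HET, 2=HOM_ALT, '.'=MISSING)

def write_genotype_matrix(
    m: GenotypeMatrix, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(SITE_COLUMNS + m.samples) + "\n")
        for i in range(m.n_sites):
            chrom, pos, ref, alt = m.sites.iloc[i][:4]
            codes = ["." if c < 0 else str(int(c)) for c in m.calls[i]]
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t" + "\t".join(codes) + "\n")


def read_genotype_matrix(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in SITE_COLUMNS]
    calls = (
        df[samples].replace(".", "-1").astype(np.int8).to_numpy()
    )
    return GenotypeMatrix(df[SITE_COLUMNS], samples, calls)


# ---------------------------------------------------------------------------
# gene models (GFF3) and sequences (FASTA)

def write_gff3_genes(
    genes: Iterable[GeneModel], path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\tb73prov\tgene\t{iv.start}\t{iv.stop}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            phase = g.cds_phase
            for k, ex in enumerate(exons, 1):
                fh.write(f"{ex.chrom}\tb73prov\texon\t{ex.start}\t{ex.stop}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n")
                fh.write(f"{ex.chrom}\tb73prov\tCDS\t{ex.start}\t{ex.stop}\t.\t"
                         f"{g.strand}\t{phase}\tID={g.gene_id}.cds{k};Parent={g.gene_id}\n")
                phase = (3 - ((ex.length - phase) % 3)) % 3


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (GenomicInterval(e.seqid, e.start, e.end)
             for e in db.children(g, featuretype="exon")),
            key=lambda iv: iv.start,
        )
        cds = sorted(db.children(g, featuretype="CDS"), key=lambda f: f.start)
        phase = 0
        if cds:
            first = cds[0] if g.strand == "+" else cds[-1]
            if first.frame not in (None, "."):
                phase = int(first.frame)
        genes.append(
            GeneModel(
                gene_id=g.id,
                interval=GenomicInterval(g.seqid, g.start, g.end),
                strand=g.strand,
                exons=exons,
                cds_phase=phase,
            )
        )
    return genes


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# expression tables

def write_expression_tsv(
    table, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    from .expression import ExpressionTable  # local to avoid cycle

    assert isinstance(table, ExpressionTable)
    df = table.genes.copy()
    for s in table.samples:
        df[s] = table.fpkm[s].to_numpy()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_expression_tsv(path: str | os.PathLike):
    from .expression import ExpressionTable

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    meta_cols = ["gene_id", "chrom", "start", "stop", "exon_length"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    fpkm = df[samples].astype(float)
    fpkm.index = df["gene_id"]
    return ExpressionTable(genes=df[meta_cols], fpkm=fpkm)
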