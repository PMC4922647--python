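"""Minimal variant-effect classification over single-transcript gene models.

Categories follow the core SnpEff vocabulary: synonymous / missense /
stop_gained / stop_lost / start_lost for coding changes, splice_donor /
splice_acceptor for the two intronic bases flanking each exon junction
(the GT-AG rule positions), noncoding for everything else inside the gene.
Splice-site and stop changes are HIGH impact, missense and start_lost
MODERATE, synonymous LOW, noncoding MODIFIER.

Gene models are strand-aware: the supplied CDS sequence is in transcript
orientation, so classifying a minus-strand SNP complements both alleles
before codon lookup.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .model import GeneModel, GenomicInterval

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

IMPACT = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
    "missense": "MODERATE",
    "start_lost": "MODERATE",
    "synonymous": "LOW",
    "noncoding": "MODIFIER",
}

HIGH_IMPACT_CATEGORIES = {"stop_gained", "stop_lost", "splice_donor", "splice_acceptor"}


@dataclass(frozen=True)
class EffectCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    category: str
    impact: str


def _splice_category(gene: GeneModel, pos: int) -> str | None:
    """splice_donor / splice_acceptor in transcript orientation, or None."""
    exons = gene.exons
    if gene.strand == "+":
        for ex in exons[:-1]:
            if ex.stop + 1 <= pos <= ex.stop + 2:
                return "splice_donor"
        for ex in exons[1:]:
            if ex.start - 2 <= pos <= ex.start - 1:
                return "splice_acceptor"
    else:
        for ex in exons[1:]:
            if ex.start - 2 <= pos <= ex.start - 1:
                return "splice_donor"
        for ex in exons[:-1]:
            if ex.stop + 1 <= pos <= ex.stop + 2:
                return "splice_acceptor"
    return None


def classify_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    cds_sequence: str,
) -> EffectCall:
    """Classify a single-nucleotide substitution against one gene model.

    ``cds_sequence`` is the spliced exon sequence in transcript orientation;
    the reference allele must agree with it at the SNP position.
    """
    if not gene.interval.contains(chrom, pos):
        raise ValueError(f"SNP {chrom}:{pos} outside gene {gene.gene_id}")
    if len(cds_sequence) != gene.exon_length:
        raise ValueError(
            f"CDS length {len(cds_sequence)} != exon length {gene.exon_length} "
            f"for {gene.gene_id}"
        )

    def call(category: str) -> EffectCall:
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, category, IMPACT[category])

    tpos = gene.transcript_position(pos)
    if tpos is None:
        splice = _splice_category(gene, pos)
        return call(splice if splice else "noncoding")

    if gene.strand == "+":
        t_ref, t_alt = ref.upper(), alt.upper()
    else:
        t_ref = ref.upper().translate(_COMPLEMENT)
        t_alt = alt.upper().translate(_COMPLEMENT)
    if cds_sequence[tpos].upper() != t_ref:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos} "
            f"(transcript pos {tpos}: CDS has {cds_sequence[tpos]!r}, expected {t_ref!r})"
        )

    cds_index = tpos - gene.cds_phase
    if cds_index < 0:
        return call("noncoding")
    codon_i = cds_index // 3
    codon_start = gene.cds_phase + codon_i * 3
    if codon_start + 3 > len(cds_sequence):
        return call("noncoding")  # incomplete trailing codon
    ref_codon = cds_sequence[codon_start:codon_start + 3].upper()
    offset = cds_index % 3
    alt_codon = ref_codon[:offset] + t_alt + ref_codon[offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return call("stop_gained")
    if ref_aa == "*" and alt_aa != "*":
        return call("stop_lost")
    if codon_i == 0 and ref_codon == "ATG":
        return call("start_lost")
    if ref_aa == alt_aa:
        return call("synonymous")
    return call("missense")


def annotate_sites(
    sites,  # DataFrame with chrom, pos, ref, alt
    genes: list[GeneModel],
    cds_sequences: dict[str, str],
) -> list[EffectCall]:
    """Classify every site falling inside a gene with an available CDS.

    Sites outside all genes, or inside genes without a sequence, are skipped.
    When genes overlap, the first gene giving a consistent exonic annotation
    wins; otherwise the first intronic/splice annotation is kept.  A site is
    only an error if it mismatches the CDS of every containing gene.
    """
    by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(
            (g.interval.start, g.interval.stop, g)
        )
    max_span: dict[str, int] = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda t: t[:2])
        max_span[chrom] = max(stop - start for start, stop, _ in lst) + 1
    out: list[EffectCall] = []
    for row in sites.itertuples(index=False):
        lst = by_chrom.get(row.chrom)
        if not lst:
            continue
        starts = [t[0] for t in lst]
        hi = bisect.bisect_right(starts, row.pos)
        lo = bisect.bisect_left(starts, row.pos - max_span[row.chrom])
        chosen: EffectCall | None = None
        error: Exception | None = None
        n_candidates = 0
        for start, stop, g in lst[lo:hi]:
            if not (start <= row.pos <= stop and g.gene_id in cds_sequences):
                continue
            n_candidates += 1
            try:
                call = classify_effect(
                    row.chrom, int(row.pos), row.ref, row.alt, g,
                    cds_sequences[g.gene_id],
                )
            except ValueError as exc:
                error = error or exc
                continue
            exonic = g.transcript_position(int(row.pos)) is not None
            if exonic:
                chosen = call
                break
            chosen = chosen or call
        if chosen is not None:
            out.append(chosen)
        elif n_candidates and error is not None:
            raise error
    return out


def summarize_effects(
    calls: list[EffectCall], regions: list[GenomicInterval]
) -> dict[str, Counter]:
    """Tallies by category, split by in/out-of-block status of the SNP."""
    out: dict[str, Counter] = {"in": Counter(), "out": Counter()}
    for c in calls:
        where = (
            "in"
            if any(r.contains(c.chrom, c.pos) for r in regions)
            else "out"
        )
        out[where][c.category] += 1
    return out
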