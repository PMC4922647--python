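# Methods

`b73prov` analyses population structure *within* a nominally uniform inbred
accession — the situation where many labs believe they are working with
genetically identical seed (the motivating case is the maize reference inbred
B73) but decades of independent propagation, backcross-derived introgressions
and residual heterozygosity have left lineages that differ in megabase-scale
haplotype blocks.  Because the only broadly available data for such cohorts
are RNA-seq experiments deposited by independent groups, every step works
from exon-limited, depth-variable evidence: per-site allele read depths
rather than genome-wide genotypes.

## Genotype classification from allele depths

For one sample at one biallelic site with `ref`, `alt` and `other` read
counts (total *n*):

* *n* < `min_depth` (default 5 reads) → MISSING;
* alt/*n* ≥ `hom_frac` (0.99) → homozygous non-reference;
* ref/*n* ≥ `hom_frac` → homozygous reference;
* (ref+alt)/*n* > `biallelic_frac` (0.90) **and** each allele > `het_allele_min`
  (0.20) → heterozygous;
* anything else → MISSING.

The classification is a total function: exactly one branch fires for every
count triple.  "99%" is interpreted inclusively (≥), "more than 90%" and
"more than 20%" strictly (>); both readings are defensible and ours is pinned
by an exhaustive test over every count combination with depth ≤ 200 against
an integer-arithmetic restatement of the rules.  One numerical point
matters: the biallelic fraction must be computed as a *single* division
`(ref+alt)/n`.  Summing the two rounded per-allele quotients can push counts
whose true sum is exactly 90% of depth over the strict threshold (e.g.
17 + 28 reads of 50 with 5 others), silently converting MISSING into HET.

`Thresholds.present_allele_min` (0.01) documents the depth at which an allele
counts as present; it never enters the decision tree because the
two-alleles-present-but-unclassifiable case already falls through to MISSING.

Sites called heterozygous in more than `max_het_sample_frac` (0.20) of *all*
samples are discarded: in an inbred cohort such sites are overwhelmingly
paralog collapse (reads from duplicated loci stacking on one reference
position), not genotype.  The denominator is the full cohort, not the
per-site genotyped subset; this is configurable.  Finally only segregating
sites (≥ 2 distinct non-missing calls) are retained.

## Phylogenetics

Distances are allele-sharing distances: mean over co-genotyped sites of
|dosage difference|/2, in [0, 1].  Trees are built by neighbor joining
(Saitou–Nei), which is consistent on additive distances and deterministic
here (Q-criterion ties break to the earliest-created pair).  NJ stands in
for likelihood or parsimony tree *search*; at 27 taxa and ~10⁴ SNPs clade
recovery, not branch-length optimality, is the requirement.  Support comes
from 100 bootstrap replicates over sites; replicates in which a sample pair
loses all shared sites are skipped and logged, and percentages are taken
over completed replicates.

Parsimony fit is summarized by the consistency and retention indices on the
NJ topology after imputation.  Per site: *m* = observed states − 1,
*s* = Fitch changes (MISSING leaves allow all states), *g* = changes on a
star tree (non-missing leaves minus the modal state count).  CI = Σm/Σs
(1.0 by convention when Σs = 0), RI = (Σg−Σs)/(Σg−Σm) over sites with
*g* ≠ *m*.  Fitch sets are folded child-by-child, which is exact for binary
trees and for the trifurcating root of an unrooted NJ tree; scores for
arbitrary multifurcations would be upper bounds.  Parsimony programs differ
in their treatment of invariant sites and missing data, so these indices
are comparable within this package rather than across implementations.

## Haplotype-block detection

A sample's non-reference calls are clustered per chromosome by
single-linkage on genomic distance: gaps ≤ `max_gap` (2 Mb) chain SNPs into
one cluster; clusters with ≥ `min_snps` (5) members become blocks spanning
their first to last SNP.  This replaces visual identification of dense
blocks with an explicit, parameter-light rule; an HMM would add nothing at
megabase scale against a background of ~1 private SNP per 10 Mb.  Note the
block *count* is not monotone in `max_gap` when `min_snps` > 1: a wider gap
can merge clusters, but it can also promote sub-threshold clusters past
`min_snps`.

Per-sample blocks overlapping across samples are merged into regions (union
of intervals).  A sample is a carrier of a region when ≥ `carrier_frac`
(0.8) of its genotyped sites inside the region are non-reference — this
recovers carriers whose own cluster narrowly missed detection and, just as
importantly, rejects coincidental overlaps of two samples' private-SNP
clusters, whose in-region non-reference fraction is diluted by all the other
segregating sites the region contains.  Regions with ≥ 2 carriers are named
`c{chrom}r{rank}`; carriers whose in-region calls are mostly heterozygous
are flagged HET.  Two summary fractions are reported side by side because
the underlying quantity ("fraction of the genome with multiple haplotypes")
has two defensible denominators: union bp of named regions over assayable
genome bp, and genes overlapping named regions over all assayed genes.

## Donor-origin assignment

Carrier consensus calls (strict per-site majority; ties → MISSING) are
compared to a donor haplotype panel restricted to the region: the nearest
haplotype by allele-sharing distance (ties reported as "no single best
match"), and an NJ placement of the consensus among the panel whose terminal
branch length summarizes residual divergence.  As an orthogonal check,
k-means with k = 2 (Lloyd's, 10 restarts, seeded) partitions samples plus
panel haplotypes on 0/1/2-coded calls in the region; on a genuine
introgression the carriers land in one cluster with their donor.

Missing data is imputed before k-means by k-nearest-neighbour majority vote
on global allele-sharing similarity — a deliberate simplification of
LD-based kNN imputers, adequate at ~10⁴ sites where genome-wide similarity
already identifies the lineage.  The default neighbour count is k = 3: the
vote must not be dominated by out-of-lineage samples when the smallest clade
has only a few members (with three clade-mates, the two remaining ones
outvote the first outside neighbour), and an odd k avoids two-way ties.
Masked-recovery on default synthetic data is flat for k ∈ {2, 3} (~94%) and
drops sharply at k = 4 for exactly this reason.  Imputation never alters
observed calls; the residual error concentrates, irreducibly, on
sample-private alleles that no neighbour carries.

## Expression bias

FPKM = counts × 10⁹ / (library size × exon length).  Genes are eligible when
mean FPKM ≥ 10 in both comparison groups.  For each eligible gene the ratio
of carrier-group median FPKM to reference-group median FPKM is taken; the
bias statistic is 1 − (median ratio over in-block genes) / (median ratio
over out-of-block genes).  Normalizing by the out-of-block stratum cancels
global differences between the two groups of datasets (lab effects, library
composition), isolating the block-linked component; the statistic is
invariant to rescaling all samples by a constant and zero when the strata
behave identically.  A difference-of-medians variant would be equally
defensible; the ratio form is used because the generative model of interest
(reduced read alignment over divergent haplotypes) is multiplicative.
Groups default to samples carrying *every* named region vs samples carrying
*none*, excluding mixed-carriage samples from both sides.

SNP density (segregating exonic SNPs per kb of exon) is correlated
(Pearson) with median expression separately for in-block and out-of-block
genes; strata with < 3 genes or zero variance are flagged undefined.

## Variant effects

A minimal effect classifier over single-transcript gene models whose exons
double as the CDS: the two intronic bases flanking each junction are
splice_donor/splice_acceptor in transcript orientation (HIGH impact); exonic
substitutions are translated ref-vs-alt codon into stop_gained/stop_lost
(HIGH), start_lost/missense (MODERATE) or synonymous (LOW); other in-gene
positions are noncoding (MODIFIER).  Classification is strand-aware
(alleles complemented for minus-strand genes) and verified strand-symmetric
by exhaustively classifying a locus and its reverse-complemented mirror.
UTRs, frameshifts (indels are excluded upstream) and overlapping isoforms
are out of scope; when gene spans overlap, the first consistent exonic
annotation wins.

## The synthetic-data generator

The generator emulates the study design the pipeline assumes, and its
defaults *are* the study conditions; they are not tuned per test.

* **Cohort**: 27 samples in a nested lineage — USA_South (subclades USDA 7,
  Iowa_State 6, UC_Berkeley 6) vs North_group (USA_North 5, China 3) — on
  10 chromosomes of 240 Mb.
* **Sites**: 13,360 segregating SNPs, 55.3% placed inside seven introgressed
  blocks with the real survey's geometry on chromosomes 2, 4, 5 and 6; the
  rest are background SNPs private to one lineage edge, weighted toward
  terminal branches (weight 1.0 vs 0.3 internal) because inbred lines
  accumulate private variants over decades of separate propagation while
  internal branches represent few generations.  All sites are placed inside
  gene exons, as RNA-seq detection requires.
* **Blocks**: each introgression is carried by a whole (sub)clade and drawn
  from one designated donor; the donor panel (103 haplotypes) contains that
  donor exactly and others diverging i.i.d. at 10% per site.  Default
  carrier sets are clade-consistent so the generating tree is identifiable;
  cross-clade haplotype sharing (the homoplasy real gene flow produces) is
  constructed explicitly in targeted tests instead.
* **Observation model**: depth per (site, sample) is negative binomial
  (mean 20, dispersion 2) scaled by the host gene's relative expression —
  coverage tracks expression, which both exercises the depth < 5 missing
  rule (~37% missing calls, realistic for RNA-seq genotyping) and induces
  the detection-bias correlation between SNP density and expression.  Reads
  are multinomial with miscall rate 1%; heterozygous truth emits 50/50
  before error.  Residual heterozygosity flips 0.2% of cells to HET.
* **Expression**: per-gene lognormal baselines (log-mean log 60, σ = 1)
  with multiplicative per-sample noise (σ = 0.2); genes inside a block are
  scaled by 1 − 0.056 in carrier samples.
* **Effects**: CDS sequences are generated deterministically per gene
  (ATG, sense codons, one stop), and site reference alleles are taken from
  the generating gene's CDS so effect classification is exactly consistent.

What the generator does *not* model: alignment and mapping artifacts (the
paralog filter is exercised on constructed fixtures, not emergent data),
recombination within blocks, linkage disequilibrium beyond block structure,
allele-specific expression, and real panel haplotype sharing.  Passing the
recovery tests therefore demonstrates the pipeline's correctness under its
own assumptions — clade-structured introgressions observed through noisy
exon-limited counts — not robustness to misalignment or reference bias.

## Problem sizes and determinism

The full default run (simulation → genotyping → 100-replicate bootstrap →
blocks → origins → expression → effects) completes in well under a minute
and is byte-identical across reruns with the same seed: all randomness
derives from one top-level seed through named substreams, k-means is
seeded, and NJ/imputation tie-breaks are deterministic.  Unit tests use a
1,500-site, flat three-clade configuration with equal branch weights; at
that scale the nested default design leaves only a handful of informative
sites per subclade edge and NJ recovery is genuinely unstable — the same
small-data effect that left the real survey's subclades weakly supported —
so study-scale claims are tested on the default configuration only.

## Known limitations

* NJ is a methodological substitute for likelihood/parsimony search; branch
  lengths in donor placements are analogues of the original workflow's
  values, not replicas.
* CI/RI depend on the tree and on missing-data conventions; values are
  comparable within this package, not across programs.
* The 90%-biallelic and 20%-paralog boundary interpretations, and the
  carrier-fraction rule, are configurable because the field's usage varies.
* Breakpoints are resolved only to the first/last observed SNP; with ~250
  SNPs per Mb-scale block the boundary error is far below `max_gap`, but
  sparse blocks will be under-called below `min_snps` observable SNPs.
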