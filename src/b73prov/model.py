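"""Core value types shared across the pipeline.

Coordinate convention: all internal coordinates are 1-based inclusive
(``GenomicInterval(chrom, start, stop)`` covers ``stop - start + 1`` bases).
BED output is the single 0-based half-open surface; the conversion lives in
:meth:`GenomicInterval.to_bed_fields` / :meth:`GenomicInterval.from_bed_fields`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise ValueError(f"stop ({self.stop}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.stop

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.stop
            and other.start <= self.stop
        )

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.stop, other.stop)
        )

    def to_bed_fields(self) -> tuple[str, int, int]:
        """(chrom, 0-based start, half-open end)."""
        return (self.chrom, self.start - 1, self.stop)

    @classmethod
    def from_bed_fields(cls, chrom: str, start0: int, end: int) -> "GenomicInterval":
        return cls(chrom, start0 + 1, end)

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.stop)


@dataclass(frozen=True)
class SiteCounts:
    """Read support for one sample at one biallelic site.

    ``other_count`` pools every read supporting neither the reference nor the
    chosen non-reference allele.
    """

    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass
class GeneModel:
    """Single-transcript gene model: exons double as the CDS.

    ``cds_phase`` is the reading-frame offset of the first CDS base in
    transcript orientation (0, 1 or 2).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds_phase not in {0, 1, 2}:
            raise ValueError("cds_phase must be 0, 1 or 2")
        prev_stop = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError("exon on different chromosome than gene")
            if prev_stop is not None and ex.start <= prev_stop:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_stop = ex.stop
        if self.exons and self.exon_length < 3:
            raise ValueError("total exon length must be >= 3")

    @property
    def exon_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    def transcript_position(self, pos: int) -> int | None:
        """0-based position of a genomic coordinate in the spliced transcript.

        Returns None for intronic/flanking positions.  Strand-aware: for
        minus-strand genes position 0 is the last base of the last exon.
        """
        offset = 0
        for ex in self.exons:
            if ex.start <= pos <= ex.stop:
                fwd = offset + (pos - ex.start)
                if self.strand == "+":
                    return fwd
                return self.exon_length - 1 - fwd
            offset += ex.length
        return None


class AlleleDepthTable:
    """Site-by-sample matrix of allele read depths.

    ``sites`` is a DataFrame with columns chrom, pos, ref, alt sorted by
    (chrom, pos); ``ref``/``alt``/``other`` are int arrays of shape
    (n_sites, n_samples).  Absent (site, sample) observations carry zero
    depth and classify downstream as MISSING.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        samples: list[str],
        ref: np.ndarray,
        alt: np.ndarray,
        other: np.ndarray,
    ) -> None:
        sites = sites.reset_index(drop=True)
        if list(sites.columns[:4]) != SITE_COLUMNS:
            raise ValueError(f"sites must have columns {SITE_COLUMNS}")
        n_sites, n_samples = len(sites), len(samples)
        for name, arr in (("ref", ref), ("alt", alt), ("other", other)):
            if arr.shape != (n_sites, n_samples):
                raise ValueError(f"{name} array shape {arr.shape} != ({n_sites}, {n_samples})")
            if arr.min(initial=0) < 0:
                raise ValueError(f"{name} counts must be non-negative")
        keys = list(zip(sites["chrom"], sites["pos"]))
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) site")
        if len(set(samples)) != n_samples:
            raise ValueError("duplicate sample names")
        self.sites = sites
        self.samples = list(samples)
        self.ref = ref
        self.alt = alt
        self.other = other

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def counts(self, site_index: int, sample: str) -> SiteCounts:
        j = self.samples.index(sample)
        return SiteCounts(
            int(self.ref[site_index, j]),
            int(self.alt[site_index, j]),
            int(self.other[site_index, j]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleDepthTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites.equals(other.sites)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.other, other.other)
        )

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, str, str, str, int, int, int]],
        samples: list[str] | None = None,
    ) -> "AlleleDepthTable":
        """Build from (chrom, pos, ref, alt, sample, ref_count, alt_count, other_count) rows.

        Raises on duplicate (site, sample) observations and on conflicting
        alleles at one position.
        """
        site_alleles: dict[tuple[str, int], tuple[str, str]] = {}
        per_cell: dict[tuple[str, int, str], tuple[int, int, int]] = {}
        sample_order: list[str] = list(samples) if samples else []
        for chrom, pos, ref, alt, sample, rc, ac, oc in records:
            key = (chrom, int(pos))
            alleles = (ref, alt)
            if key in site_alleles and site_alleles[key] != alleles:
                raise ValueError(f"conflicting alleles at {chrom}:{pos}")
            site_alleles[key] = alleles
            cell = (chrom, int(pos), sample)
            if cell in per_cell:
                raise ValueError(f"duplicate record for {chrom}:{pos} sample {sample}")
            per_cell[cell] = (int(rc), int(ac), int(oc))
            if sample not in sample_order:
                if samples is not None:
                    raise ValueError(f"unknown sample {sample!r}")
                sample_order.append(sample)
        site_keys = sorted(site_alleles)
        sites = pd.DataFrame(
            [(c, p, *site_alleles[(c, p)]) for c, p in site_keys],
            columns=SITE_COLUMNS,
        )
        n_sites = len(site_keys)
        shape = (n_sites, len(sample_order))
        ref_a = np.zeros(shape, dtype=np.int64)
        alt_a = np.zeros(shape, dtype=np.int64)
        oth_a = np.zeros(shape, dtype=np.int64)
        site_idx = {k: i for i, k in enumerate(site_keys)}
        samp_idx = {s: j for j, s in enumerate(sample_order)}
        for (chrom, pos, sample), (rc, ac, oc) in per_cell.items():
            i, j = site_idx[(chrom, pos)], samp_idx[sample]
            ref_a[i, j], alt_a[i, j], oth_a[i, j] = rc, ac, oc
        return cls(sites, sample_order, ref_a, alt_a, oth_a)
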