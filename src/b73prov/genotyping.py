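"""Allele-depth genotype classification and the genotype matrix.

Genotypes are classified per (site, sample) from raw read support:

* total depth below ``min_depth`` -> MISSING
* non-reference reads make up at least ``hom_frac`` of all reads -> HOM_ALT
* reference reads make up at least ``hom_frac`` -> HOM_REF
* ref+alt exceed ``biallelic_frac`` of all reads and each allele exceeds
  ``het_allele_min`` -> HET
* anything else -> MISSING

A site heterozygous in more than ``max_het_sample_frac`` of all samples is
discarded as a likely paralog-collapse artifact (reads from duplicated loci
mapping to one reference position mimic heterozygosity in everyone).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlleleDepthTable, GenomicInterval, SiteCounts, SITE_COLUMNS


class GenotypeCall(enum.IntEnum):
    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


MISSING = np.int8(GenotypeCall.MISSING)


@dataclass(frozen=True)
class Thresholds:
    """Classification constants.

    ``present_allele_min`` documents the minimum fraction at which an allele
    is considered present; sites where two alleles clear it without
    satisfying the homozygous or heterozygous rules fall through to MISSING,
    so the value never enters the decision tree explicitly.
    """

    min_depth: int = 5
    hom_frac: float = 0.99
    biallelic_frac: float = 0.90
    het_allele_min: float = 0.20
    present_allele_min: float = 0.01
    max_het_sample_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("hom_frac", "biallelic_frac", "het_allele_min",
                     "present_allele_min", "max_het_sample_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.hom_frac <= 0.5:
            raise ValueError("hom_frac must exceed 0.5 so HOM calls are unambiguous")


def classify_site(counts: SiteCounts, t: Thresholds = Thresholds()) -> GenotypeCall:
    """Classify one (site, sample) observation. Total function: every input
    yields exactly one category."""
    total = counts.total
    if total < t.min_depth:
        return GenotypeCall.MISSING
    ref_f = counts.ref_count / total
    alt_f = counts.alt_count / total
    biallelic_f = (counts.ref_count + counts.alt_count) / total  # single division:
    # summing ref_f + alt_f can round an exact 90% over the strict threshold
    if alt_f >= t.hom_frac:
        return GenotypeCall.HOM_ALT
    if ref_f >= t.hom_frac:
        return GenotypeCall.HOM_REF
    if biallelic_f > t.biallelic_frac and ref_f > t.het_allele_min and alt_f > t.het_allele_min:
        return GenotypeCall.HET
    return GenotypeCall.MISSING


def classify_array(
    ref: np.ndarray, alt: np.ndarray, other: np.ndarray, t: Thresholds = Thresholds()
) -> np.ndarray:
    """Vectorized :func:`classify_site` over parallel count arrays (int8 codes)."""
    total = ref + alt + other
    safe = np.maximum(total, 1).astype(float)
    ref_f = ref / safe
    alt_f = alt / safe
    out = np.full(total.shape, MISSING, dtype=np.int8)
    biallelic_f = (ref + alt) / safe
    het = (
        (biallelic_f > t.biallelic_frac)
        & (ref_f > t.het_allele_min)
        & (alt_f > t.het_allele_min)
    )
    out[het] = GenotypeCall.HET
    out[ref_f >= t.hom_frac] = GenotypeCall.HOM_REF
    out[alt_f >= t.hom_frac] = GenotypeCall.HOM_ALT
    out[total < t.min_depth] = MISSING
    return out


class GenotypeMatrix:
    """Sites x samples grid of genotype calls.

    ``calls`` is an int8 array with codes 0 = HOM_REF, 1 = HET, 2 = HOM_ALT,
    -1 = MISSING; the 0/1/2 coding doubles as non-reference allele dosage.
    """

    def __init__(self, sites: pd.DataFrame, samples: list[str], calls: np.ndarray) -> None:
        sites = sites.reset_index(drop=True)
        if list(sites.columns[:4]) != SITE_COLUMNS:
            raise ValueError(f"sites must have columns {SITE_COLUMNS}")
        if calls.shape != (len(sites), len(samples)):
            raise ValueError("calls shape does not match sites x samples")
        if not np.isin(calls, [-1, 0, 1, 2]).all():
            raise ValueError("calls must be coded -1/0/1/2")
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"site positions not strictly increasing on {chrom}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names")
        self.sites = sites
        self.samples = list(samples)
        self.calls = calls.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def site_interval(self, i: int) -> GenomicInterval:
        row = self.sites.iloc[i]
        return GenomicInterval(row["chrom"], int(row["pos"]), int(row["pos"]))

    def region_mask(self, region: GenomicInterval) -> np.ndarray:
        """Boolean mask of sites inside a 1-based inclusive interval."""
        return (
            (self.sites["chrom"] == region.chrom)
            & (self.sites["pos"] >= region.start)
            & (self.sites["pos"] <= region.stop)
        ).to_numpy()

    def regions_mask(self, regions: list[GenomicInterval]) -> np.ndarray:
        mask = np.zeros(self.n_sites, dtype=bool)
        for r in regions:
            mask |= self.region_mask(r)
        return mask

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.loc[mask], self.samples, self.calls[mask])

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(self.sites, list(samples), self.calls[:, idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.copy(), list(self.samples), self.calls.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites.equals(other.sites)
            and np.array_equal(self.calls, other.calls)
        )


def build_matrix(depths: AlleleDepthTable, t: Thresholds = Thresholds()) -> GenotypeMatrix:
    """Classify every (site, sample) cell of an allele-depth table."""
    if depths.n_sites == 0:
        raise ValueError("empty allele-depth table")
    calls = classify_array(depths.ref, depths.alt, depths.other, t)
    return GenotypeMatrix(depths.sites, depths.samples, calls)


def paralog_filter(m: GenotypeMatrix, t: Thresholds = Thresholds()) -> GenotypeMatrix:
    """Drop sites heterozygous in more than ``max_het_sample_frac`` of all
    samples (strict >; the denominator is the full cohort)."""
    het_frac = (m.calls == GenotypeCall.HET).sum(axis=1) / m.n_samples
    return m.subset_sites(het_frac <= t.max_het_sample_frac)


def segregating_sites(m: GenotypeMatrix) -> GenotypeMatrix:
    """Retain sites showing at least two distinct non-missing genotypes."""
    present = np.stack([(m.calls == c).any(axis=1) for c in (0, 1, 2)])
    keep = present.sum(axis=0) >= 2
    return m.subset_sites(keep)


def concordance(observed: GenotypeMatrix, truth: GenotypeMatrix) -> float:
    """Fraction of observed non-missing calls that match the truth matrix.

    Both matrices must share site order and samples.
    """
    if observed.samples != truth.samples or observed.n_sites != truth.n_sites:
        raise ValueError("matrices are not aligned")
    mask = (observed.calls != MISSING) & (truth.calls != MISSING)
    if not mask.any():
        return float("nan")
    return float((observed.calls[mask] == truth.calls[mask]).mean())
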