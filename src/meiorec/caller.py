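"""Crossover breakpoint detection in BC1 backcross individuals.

The offspring of an F1 (Col-0/Ws) backcrossed to Col-0 carry chromosomes
that are mosaics of heterozygous (Col/Ws) and homozygous-Col blocks; each
block boundary is a crossover that occurred in the F1 meiosis.  At the
1–9x coverage typical of such screens, per-SNP genotypes are unreliable,
so evidence is pooled: 100 adjacent informative SNPs form a bin, and the
bin's zygosity is read off the pooled heterozygosity score

    h = 2 R A / (R + A)^2

where R and A are the summed reads supporting the Col-0 (reference) and
Ws (alternative) allele over the bin.  h is near 0.5 in heterozygous and
near 0 in homozygous regions.  Bins with h < 0.05 are called HOM, bins
with h > 0.45 HET, anything else UNDET.  Traversing determined bins along
a chromosome, every HOM<->HET switch is one crossover; the breakpoint is
localised to the interval between the last SNP of the left determined bin
and the first SNP of the right determined bin, with intervening UNDET
bins widening the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "HOM",
    "HET",
    "UNDET",
    "AlleleCounts",
    "Bin",
    "CrossoverCall",
    "COSummary",
    "pooled_heterozygosity",
    "select_informative_sites",
    "bin_snps",
    "classify_bin",
    "call_crossovers",
    "call_sample",
    "summarize_cos",
]

HOM = "HOM"
HET = "HET"
UNDET = "UNDET"

# Genotype codes for informative-site selection.
HOM_REF = "HOM_REF"
HOM_ALT = "HOM_ALT"
GT_HET = "HET"
MISSING = "MISSING"


@dataclass
class AlleleCounts:
    """Per-SNP allele read counts for one sample.

    ``table`` has columns ``chrom`` (str), ``pos`` (1-based int), ``ref``
    (reads supporting the Col-0/reference allele) and ``alt`` (reads
    supporting the Ws/alternative allele), sorted by (chrom, pos).
    """

    table: pd.DataFrame
    sample_id: str = "sample"
    n_skipped: int = 0  # non-biallelic / non-SNP records dropped at input

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"allele count table must have columns {sorted(required)}")
        t = self.table
        if (t["ref"] < 0).any() or (t["alt"] < 0).any():
            raise ValueError("negative read counts")
        for chrom, sub in t.groupby("chrom", sort=False):
            d = np.diff(sub["pos"].to_numpy())
            if d.size and not np.all(d > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class Bin:
    """A window of adjacent SNPs with pooled allele counts."""

    chrom: str
    index: int
    first_snp_pos: int
    last_snp_pos: int
    n_snps: int
    R_sum: int
    A_sum: int
    zygosity: str = UNDET
    ws_flag: bool = False  # looks homozygous for the Ws allele: impossible in BC1

    @property
    def h(self) -> float | None:
        """Pooled heterozygosity of the bin; None when the bin has no reads."""
        if self.R_sum + self.A_sum == 0:
            return None
        return pooled_heterozygosity(self.R_sum, self.A_sum)


@dataclass
class CrossoverCall:
    chrom: str
    left_pos: int  # last SNP of the left determined bin (1-based)
    right_pos: int  # first SNP of the right determined bin (1-based)
    left_class: str
    right_class: str
    n_undetermined_spanned: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left_pos must be < right_pos")
        if self.left_class == self.right_class:
            raise ValueError("crossover call requires a zygosity change")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left_pos + self.right_pos)


@dataclass
class COSummary:
    per_sample_per_chrom: pd.DataFrame  # index sample, columns chromosome names
    totals: pd.Series  # per-sample genome totals
    multi_co_fraction: float  # fraction of (sample, chromosome) pairs with >= 2 COs
    arm_position_hist: np.ndarray  # counts over [0, 1], 0 = centromere, 1 = telomere
    arm_position_edges: np.ndarray

    @property
    def mean_cos_per_genome(self) -> float:
        return float(self.totals.mean()) if len(self.totals) else 0.0

    @property
    def sd_cos_per_genome(self) -> float:
        return float(self.totals.std(ddof=1)) if len(self.totals) > 1 else 0.0


def pooled_heterozygosity(R, A):
    """Pooled heterozygosity score h = 2RA/(R+A)^2.

    Accepts scalars or arrays; the total read count must be positive at
    every position evaluated.  h lies in [0, 0.5], is symmetric in R and
    A, reaches 0.5 when R = A and 0 when either count is zero.
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(R < 0) or np.any(A < 0):
        raise ValueError("read counts must be non-negative")
    total = R + A
    if np.any(total == 0):
        raise ValueError("pooled heterozygosity undefined for zero total reads")
    h = 2.0 * R * A / total**2
    return float(h) if h.ndim == 0 else h


def select_informative_sites(
    parent_ref_gt: Sequence[str],
    parent_alt_gt: Sequence[str],
    f1_gt: Sequence[str],
    allow_mirrored: bool = True,
) -> np.ndarray:
    """Mask of "homozygous unique" SNPs.

    A site is informative when it is homozygous in each parental accession
    (for opposite alleles) and heterozygous in the F1 hybrid.  With
    ``allow_mirrored`` the parental arrangement may be swapped
    (parent1 HOM_ALT / parent2 HOM_REF).
    """
    p1 = np.asarray(parent_ref_gt, dtype=object)
    p2 = np.asarray(parent_alt_gt, dtype=object)
    f1 = np.asarray(f1_gt, dtype=object)
    if not (p1.shape == p2.shape == f1.shape):
        raise ValueError("genotype vectors must have equal length")
    keep = (p1 == HOM_REF) & (p2 == HOM_ALT) & (f1 == GT_HET)
    if allow_mirrored:
        keep |= (p1 == HOM_ALT) & (p2 == HOM_REF) & (f1 == GT_HET)
    return keep


def bin_snps(counts: AlleleCounts, bin_size: int = 100, min_tail: int = 50) -> list[Bin]:
    """Partition each chromosome into consecutive windows of ``bin_size`` SNPs.

    A terminal remainder of at least ``min_tail`` SNPs forms its own bin;
    a shorter remainder is merged into the preceding bin.  Bins pool read
    counts over their SNPs; classification happens separately.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins: list[Bin] = []
    for chrom, sub in counts.table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        R = sub["ref"].to_numpy()
        A = sub["alt"].to_numpy()
        n = pos.size
        if n == 0:
            continue
        edges = list(range(0, n, bin_size))
        starts = edges
        stops = [min(s + bin_size, n) for s in starts]
        # merge a short terminal remainder backward
        if len(starts) > 1 and stops[-1] - starts[-1] < min_tail:
            stops[-2] = stops[-1]
            starts = starts[:-1]
            stops = stops[:-1]
        for i, (s, e) in enumerate(zip(starts, stops)):
            bins.append(
                Bin(
                    chrom=str(chrom),
                    index=i,
                    first_snp_pos=int(pos[s]),
                    last_snp_pos=int(pos[e - 1]),
                    n_snps=e - s,
                    R_sum=int(R[s:e].sum()),
                    A_sum=int(A[s:e].sum()),
                )
            )
    return bins


def classify_bin(
    bin: Bin,
    hom_max: float = 0.05,
    het_min: float = 0.45,
    min_reads: int = 1,
) -> str:
    """Classify a bin as HOM, HET or UNDET from its pooled h.

    Strict inequalities: h < hom_max gives HOM, h > het_min HET,
    everything else (including h exactly on a threshold, no reads, or
    fewer than ``min_reads`` reads) UNDET.  A bin that looks homozygous
    for the Ws allele (h below hom_max with alt reads dominating) is
    impossible in a Col-0 backcross and is flagged as likely
    contamination or sample mix-up, but still classified HOM.
    """
    total = bin.R_sum + bin.A_sum
    if total < max(min_reads, 1):
        bin.zygosity = UNDET
        return UNDET
    h = pooled_heterozygosity(bin.R_sum, bin.A_sum)
    if h < hom_max:
        cls = HOM
        if bin.A_sum > bin.R_sum:
            bin.ws_flag = True
            logger.warning(
                "%s bin %d: homozygous-Ws signature (R=%d, A=%d); "
                "possible contamination or sample mix-up",
                bin.chrom,
                bin.index,
                bin.R_sum,
                bin.A_sum,
            )
    elif h > het_min:
        cls = HET
    else:
        cls = UNDET
    bin.zygosity = cls
    return cls


def call_crossovers(bins: Iterable[Bin], sample_id: str | None = None) -> list[CrossoverCall]:
    """Emit one crossover call per zygosity switch between determined bins.

    UNDET bins never emit or suppress calls; they only widen the reported
    breakpoint interval (counted in ``n_undetermined_spanned``).  Bins
    must already be classified and ordered along each chromosome.
    """
    calls: list[CrossoverCall] = []
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, chrom_bins in by_chrom.items():
        prev: Bin | None = None
        n_undet = 0
        for b in chrom_bins:
            if b.zygosity == UNDET:
                if prev is not None:
                    n_undet += 1
                continue
            if prev is not None and b.zygosity != prev.zygosity:
                calls.append(
                    CrossoverCall(
                        chrom=chrom,
                        left_pos=prev.last_snp_pos,
                        right_pos=b.first_snp_pos,
                        left_class=prev.zygosity,
                        right_class=b.zygosity,
                        n_undetermined_spanned=n_undet,
                        sample_id=sample_id or "sample",
                    )
                )
            prev = b
            n_undet = 0
    return calls


def call_sample(
    counts: AlleleCounts,
    bin_size: int = 100,
    min_tail: int = 50,
    hom_max: float = 0.05,
    het_min: float = 0.45,
    min_reads: int = 1,
) -> tuple[list[CrossoverCall], list[Bin]]:
    """Bin, classify and call crossovers for one sample."""
    bins = bin_snps(counts, bin_size=bin_size, min_tail=min_tail)
    for b in bins:
        classify_bin(b, hom_max=hom_max, het_min=het_min, min_reads=min_reads)
    return call_crossovers(bins, sample_id=counts.sample_id), bins


def summarize_cos(
    calls: Iterable[CrossoverCall],
    genome: GenomeModel,
    sample_ids: Sequence[str],
    n_hist_bins: int = 10,
) -> COSummary:
    """Per-sample/per-chromosome CO counts and the arm-position spectrum.

    The arm-position histogram places each CO interval midpoint on its
    chromosome arm at |mid - centromere| / |telomere - centromere|, so 0
    is the centromere and 1 the telomere, pooling all arms.
    """
    chrom_names = genome.names
    counts = pd.DataFrame(0, index=list(sample_ids), columns=chrom_names, dtype=int)
    positions: list[float] = []
    for call in calls:
        chrom = genome[call.chrom]
        mid = call.midpoint
        if not (1 <= mid <= chrom.length_bp):
            raise ValueError(f"CO midpoint {mid} outside {call.chrom}")
        counts.loc[call.sample_id, call.chrom] += 1
        cen = chrom.centromere_bp
        if mid >= cen:
            denom = chrom.length_bp - cen
        else:
            denom = cen - 1
        positions.append(abs(mid - cen) / denom if denom > 0 else 0.0)
    hist, edges = np.histogram(positions, bins=n_hist_bins, range=(0.0, 1.0))
    totals = counts.sum(axis=1)
    n_pairs = counts.size
    multi = float((counts.to_numpy() >= 2).sum() / n_pairs) if n_pairs else 0.0
    return COSummary(
        per_sample_per_chrom=counts,
        totals=totals,
        multi_co_fraction=multi,
        arm_position_hist=hist,
        arm_position_edges=edges,
    )
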