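"""File input/output for every pipeline artefact.

Formats:

* allele counts — 4-column TSV ``chrom  pos  ref_count  alt_count`` or
  minimal VCFv4.2 with a per-sample ``AD`` FORMAT field (read via
  cyvcf2; only biallelic SNPs are used, everything else is skipped with
  a logged tally);
* crossover calls — BED-like TSV with 0-based half-open intervals;
* ground-truth crossovers — BED-like TSV;
* tetrads and pollen — CSV (one row per tetrad with 12 spore-by-marker
  booleans / one row per pollen grain);
* spot images — 16-bit grayscale TIFF with a JSON sidecar of true
  centers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import AlleleCounts, CrossoverCall
from .synthetic import SPORE_MARKER_COLUMNS, MeiosisTruth, SpotGroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_allele_counts",
    "write_allele_counts_tsv",
    "write_allele_counts_vcf",
    "write_crossovers",
    "read_crossovers",
    "write_truth_bed",
    "write_tetrads_csv",
    "read_tetrads_csv",
    "write_pollen_csv",
    "read_pollen_csv",
    "write_spot_image",
    "read_spot_image",
]


class FormatError(ValueError):
    """Malformed or unsupported input file."""


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------


def read_allele_counts(path: str | Path, sample: str | None = None) -> AlleleCounts:
    """Read per-SNP allele counts from VCF (``.vcf``) or 4-column TSV.

    For VCF the per-sample ``AD`` field supplies (ref, alt) read counts;
    multiallelic and non-SNP records are skipped and tallied.  Positions
    must be strictly increasing within each chromosome.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        return _read_allele_counts_vcf(path, sample)
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 tab-separated columns, got {df.shape[1]}")
    # accept files with or without a header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["chrom", "pos", "ref", "alt"]
    df = df.astype({"chrom": str, "pos": np.int64, "ref": np.int64, "alt": np.int64})
    try:
        return AlleleCounts(table=df, sample_id=sample or path.stem)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_allele_counts_vcf(path: Path, sample: str | None) -> AlleleCounts:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    if sample is None:
        sample = samples[0]
    if sample not in samples:
        raise FormatError(f"{path}: sample {sample!r} not in VCF ({samples})")
    si = samples.index(sample)
    rows = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD")
        ref_n, alt_n = int(ad[si][0]), int(ad[si][1])
        if ref_n < 0 or alt_n < 0:  # missing AD encodes as negative
            ref_n = max(ref_n, 0)
            alt_n = max(alt_n, 0)
        rows.append((rec.CHROM, rec.POS, ref_n, alt_n))
    if skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP records", path, skipped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    try:
        counts = AlleleCounts(table=df, sample_id=sample)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    counts.n_skipped = skipped
    return counts


def write_allele_counts_tsv(counts: AlleleCounts, path: str | Path) -> None:
    counts.table.to_csv(path, sep="\t", header=False, index=False)


def write_allele_counts_vcf(counts: AlleleCounts, path: str | Path, contigs=None) -> None:
    """Write counts as a minimal single-sample VCFv4.2 with an AD FORMAT field.

    Alleles are placeholders (A/T); only positions and read counts carry
    information.  ``contigs`` may map chromosome name to length.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{counts.sample_id}\n"
        )
        for chrom, pos, r, a in counts.table.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT:AD\t./.:{r},{a}\n")


# ---------------------------------------------------------------------------
# Crossover calls and truth
# ---------------------------------------------------------------------------

_CO_COLUMNS = ["chrom", "start", "end", "sample", "left_class", "right_class", "n_undet"]


def write_crossovers(calls, path: str | Path) -> None:
    """Write calls as BED-like TSV: 0-based half-open [left_pos-1, right_pos)."""
    rows = [
        (
            c.chrom,
            c.left_pos - 1,
            c.right_pos,
            c.sample_id,
            c.left_class,
            c.right_class,
            c.n_undetermined_spanned,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=_CO_COLUMNS)
    df = df.sort_values(["chrom", "start", "sample"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_crossovers(path: str | Path) -> list[CrossoverCall]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _CO_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(df.columns)}")
    return [
        CrossoverCall(
            chrom=str(r.chrom),
            left_pos=int(r.start) + 1,
            right_pos=int(r.end),
            left_class=str(r.left_class),
            right_class=str(r.right_class),
            n_undetermined_spanned=int(r.n_undet),
            sample_id=str(r.sample),
        )
        for r in df.itertuples(index=False)
    ]


def write_truth_bed(truth: MeiosisTruth, path: str | Path, sample_id: str = "sim") -> None:
    """Ground-truth crossover positions as BED-like TSV (0-based starts)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\tstart_phase\n")
        for chrom, positions in truth.co_positions_bp.items():
            phase = truth.start_phase[chrom]
            for p in positions:
                fh.write(f"{chrom}\t{int(p) - 1}\t{int(p)}\t{sample_id}\t{phase}\n")


# ---------------------------------------------------------------------------
# Tetrads / pollen
# ---------------------------------------------------------------------------


def write_tetrads_csv(tetrads: pd.DataFrame, path: str | Path) -> None:
    tetrads.to_csv(path, index=False)


def read_tetrads_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["tetrad_id", *SPORE_MARKER_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for c in SPORE_MARKER_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def write_pollen_csv(pollen: pd.DataFrame, path: str | Path) -> None:
    pollen.to_csv(path, index=False)


def read_pollen_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("pollen_id", "mA", "mB") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["mA"] = df["mA"].astype(bool)
    df["mB"] = df["mB"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Spot images
# ---------------------------------------------------------------------------


def write_spot_image(gt: SpotGroundTruth, path: str | Path) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar with the true centers."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, gt.image)
    sidecar = {
        "true_centers": [[float(r), float(c)] for r, c in gt.true_centers],
        "amplitude": gt.amplitude,
        "background": gt.background,
        "noise_sd": gt.noise_sd,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_spot_image(path: str | Path) -> np.ndarray:
    import tifffile

    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D grayscale image")
    return img
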