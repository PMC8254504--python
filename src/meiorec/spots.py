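"""Single-molecule spot counting and oligo/protein quantification.

Surface-immobilised SPO11 (or Rec12) molecules imaged by TIRF appear as
diffraction-limited spots on 16-bit frames.  Spots are counted as
intensity maxima with a *noise tolerance* (prominence) criterion that
mirrors ImageJ's "Find Maxima": candidate local maxima are processed in
decreasing intensity; from each candidate a region floods over
8-connected pixels brighter than (peak - tolerance); a candidate whose
region reaches a previously claimed higher maximum, or a brighter
pixel, is absorbed rather than counted; an equal-intensity plateau
yields a single maximum at its centroid.  Maxima sitting on the
outermost pixel frame are optionally discarded (border exclusion).

The meiotically active fraction per genotype is the summed oligo-channel
maxima divided by the summed total-protein maxima, each normalised by
its lysate volume; genotype effects are reported as fold changes of
these fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MaximaSet",
    "QuantBatch",
    "FoldChangeResult",
    "find_maxima",
    "count_maxima",
    "oligo_fraction",
    "oligo_fraction_from_counts",
    "fold_change",
]


@dataclass
class MaximaSet:
    coords: np.ndarray  # (k, 2) int array of (row, col)
    tolerance: float
    border_excluded: bool

    @property
    def count(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class QuantBatch:
    """Images and lysate volumes of one genotype's oligo/protein assay."""

    genotype: str
    oligo_images: list[np.ndarray]
    protein_images: list[np.ndarray]
    lysate_volume_oligo: float = 1.0
    lysate_volume_protein: float = 1.0

    def __post_init__(self) -> None:
        if self.lysate_volume_oligo <= 0 or self.lysate_volume_protein <= 0:
            raise ValueError("lysate volumes must be positive")
        if not self.oligo_images or not self.protein_images:
            raise ValueError("need at least one image per channel")


@dataclass
class FoldChangeResult:
    fraction_mutant: float
    fraction_wildtype: float
    fold_change: float
    replicate_ratios: list[float] | None = None
    replicate_mean: float | None = None
    replicate_sd: float | None = None


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_maxima(
    image: np.ndarray,
    noise_tolerance: float = 6000,
    exclude_border: bool = True,
) -> MaximaSet:
    """ImageJ-compatible prominence maxima of a 2-D image.

    Pixels at the global minimum never seed maxima (a constant image has
    none).  Plateau centroids are rounded toward the top-left on exact
    halves.  With ``exclude_border`` maxima on the outermost pixel
    row/column are discarded after detection.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if noise_tolerance < 0:
        raise ValueError("noise tolerance must be >= 0")
    img = img.astype(np.float64, copy=False)
    nrow, ncol = img.shape
    global_min = img.min()
    # candidate local maxima: >= all 8 neighbours and above the global minimum
    local_max = ndimage.maximum_filter(img, size=3, mode="nearest") == img
    local_max &= img > global_min
    cand = np.argwhere(local_max)
    if cand.size:
        values = img[cand[:, 0], cand[:, 1]]
        order = np.lexsort((cand[:, 1], cand[:, 0], -values))
        cand = cand[order]
    processed = np.zeros(img.shape, dtype=bool)
    in_region = np.zeros(img.shape, dtype=bool)
    maxima: list[tuple[int, int]] = []
    for r0, c0 in cand:
        if processed[r0, c0]:
            continue
        v0 = img[r0, c0]
        floor = v0 - noise_tolerance
        region: list[tuple[int, int]] = [(r0, c0)]
        in_region[r0, c0] = True
        stack = [(r0, c0)]
        absorbed = False
        plateau_r = plateau_c = n_plateau = 0
        while stack:
            r, c = stack.pop()
            if img[r, c] == v0:
                plateau_r += r
                plateau_c += c
                n_plateau += 1
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= nrow or cc < 0 or cc >= ncol or in_region[rr, cc]:
                    continue
                v = img[rr, cc]
                if v > v0 or processed[rr, cc]:
                    # within tolerance-reach of a higher or earlier peak
                    absorbed = True
                    continue
                if v > floor:
                    in_region[rr, cc] = True
                    region.append((rr, cc))
                    stack.append((rr, cc))
        for r, c in region:
            processed[r, c] = True
            in_region[r, c] = False
        if not absorbed:
            # plateau centroid, half-values rounded toward the top-left
            mr = math.ceil(plateau_r / n_plateau - 0.5)
            mc = math.ceil(plateau_c / n_plateau - 0.5)
            maxima.append((mr, mc))
    coords = np.asarray(maxima, dtype=int).reshape(-1, 2)
    if exclude_border and coords.size:
        interior = (
            (coords[:, 0] > 0)
            & (coords[:, 0] < nrow - 1)
            & (coords[:, 1] > 0)
            & (coords[:, 1] < ncol - 1)
        )
        coords = coords[interior]
    return MaximaSet(coords=coords, tolerance=float(noise_tolerance), border_excluded=exclude_border)


def count_maxima(
    images: Sequence[np.ndarray],
    noise_tolerance: float = 6000,
    exclude_border: bool = True,
) -> int:
    """Summed maxima count over a sequence of images."""
    return sum(
        find_maxima(im, noise_tolerance, exclude_border).count for im in images
    )


def oligo_fraction(
    batch: QuantBatch,
    noise_tolerance: float = 6000,
    exclude_border: bool = True,
) -> float:
    """Volume-normalised oligo/protein maxima ratio of one genotype.

    fraction = (sum of oligo maxima / oligo lysate volume)
             / (sum of protein maxima / protein lysate volume)
    """
    oligo = count_maxima(batch.oligo_images, noise_tolerance, exclude_border)
    protein = count_maxima(batch.protein_images, noise_tolerance, exclude_border)
    return oligo_fraction_from_counts(
        oligo, protein, batch.lysate_volume_oligo, batch.lysate_volume_protein
    )


def oligo_fraction_from_counts(
    oligo_total: int,
    protein_total: int,
    lysate_volume_oligo: float = 1.0,
    lysate_volume_protein: float = 1.0,
) -> float:
    if lysate_volume_oligo <= 0 or lysate_volume_protein <= 0:
        raise ValueError("lysate volumes must be positive")
    if protein_total == 0:
        raise ZeroDivisionError("no protein maxima: oligo fraction undefined")
    return (oligo_total / lysate_volume_oligo) / (protein_total / lysate_volume_protein)


def fold_change(
    mutant_fraction: float | Sequence[float],
    wildtype_fraction: float | Sequence[float],
) -> FoldChangeResult:
    """Ratio of mutant to wild-type oligo fractions.

    When per-replicate fractions are supplied (paired sequences of equal
    length), the per-replicate ratios and their mean and SD are reported
    alongside the pooled fold change (ratio of replicate means).
    """
    mut = np.atleast_1d(np.asarray(mutant_fraction, dtype=float))
    wt = np.atleast_1d(np.asarray(wildtype_fraction, dtype=float))
    replicate_ratios = replicate_mean = replicate_sd = None
    if mut.size > 1 or wt.size > 1:
        if mut.size != wt.size:
            raise ValueError("replicate fraction lists must be paired (equal length)")
        if np.any(wt == 0):
            raise ZeroDivisionError("wild-type replicate fraction of zero")
        ratios = mut / wt
        replicate_ratios = [float(x) for x in ratios]
        replicate_mean = float(ratios.mean())
        replicate_sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    f_mut, f_wt = float(mut.mean()), float(wt.mean())
    if f_wt == 0:
        raise ZeroDivisionError("wild-type fraction of zero: fold change undefined")
    return FoldChangeResult(
        fraction_mutant=f_mut,
        fraction_wildtype=f_wt,
        fold_change=f_mut / f_wt,
        replicate_ratios=replicate_ratios,
        replicate_mean=replicate_mean,
        replicate_sd=replicate_sd,
    )
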