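"""Tetrad and single-pollen recombination genetics.

Fluorescent-tagged lines carry hemizygous pollen-expressed fluorophore
transgenes; in a quartet (qrt) background the four pollen grains of one
meiosis stay attached, so every tetrad can be scored for marker
presence.  For a two-marker interval each valid tetrad (2:2 segregation
per marker) is a parental ditype (PD), tetratype (TT) or non-parental
ditype (NPD), and the map distance follows Perkins' formula

    cM = 100 * (TT/2 + 3*NPD) / n .

Crossover interference between two adjacent intervals is summarised by
the interference ratio (IFR): the focal interval's map distance among
tetrads *with* a crossover in the adjacent interval divided by the map
distance among tetrads *without* one.  IFR < 1 indicates interference,
IFR > 1 crossover clustering.

Single pollen grains scored for the two markers flanking one interval
give the recombinant fraction directly: cM = 100 * recombinants / n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PD",
    "TT",
    "NPD",
    "MalformedTetradError",
    "UndefinedRatioError",
    "DistanceResult",
    "InterferenceResult",
    "PollenDistance",
    "interval_ditype",
    "classify_intervals",
    "perkins_distance",
    "interference_ratio",
    "tetrad_event_spectrum",
    "single_pollen_distance",
    "fisher_recombination_test",
]

PD = "PD"
TT = "TT"
NPD = "NPD"


class MalformedTetradError(ValueError):
    """A tetrad violating 2:2 marker segregation."""


class UndefinedRatioError(ZeroDivisionError):
    """An interference ratio whose numerator or denominator subgroup is empty
    or has zero map distance in the denominator."""


@dataclass
class DistanceResult:
    interval: str
    n: int
    pd: int
    tt: int
    npd: int
    cM: float
    n_malformed: int = 0


@dataclass
class InterferenceResult:
    focal: str
    adjacent: str
    with_adjacent_co: DistanceResult
    without_adjacent_co: DistanceResult
    ifr: float

    @property
    def cM_with(self) -> float:
        return self.with_adjacent_co.cM

    @property
    def cM_without(self) -> float:
        return self.without_adjacent_co.cM


@dataclass
class PollenDistance:
    n: int
    recombinant: int
    cM: float


def _marker_matrix(tetrads: pd.DataFrame, marker: str) -> np.ndarray:
    cols = [f"s{s}_{marker}" for s in (1, 2, 3, 4)]
    missing = [c for c in cols if c not in tetrads.columns]
    if missing:
        raise KeyError(f"tetrad table lacks columns {missing}")
    return tetrads[cols].to_numpy(dtype=bool)


def classify_intervals(
    tetrads: pd.DataFrame, marker_i: str = "m1", marker_j: str = "m2"
) -> tuple[pd.Series, np.ndarray]:
    """Vectorised per-tetrad ditype classification for one interval.

    Returns the ditype label per tetrad (NaN where malformed) and a
    boolean validity mask.  A tetrad is valid iff both markers segregate
    2:2; the interval class is then determined by how many spores carry
    both markers: 2 -> PD, 1 -> TT, 0 -> NPD.
    """
    mi = _marker_matrix(tetrads, marker_i)
    mj = _marker_matrix(tetrads, marker_j)
    valid = (mi.sum(axis=1) == 2) & (mj.sum(axis=1) == 2)
    n11 = (mi & mj).sum(axis=1)
    labels = np.full(len(tetrads), None, dtype=object)
    labels[valid & (n11 == 2)] = PD
    labels[valid & (n11 == 1)] = TT
    labels[valid & (n11 == 0)] = NPD
    return pd.Series(labels, index=tetrads.index), valid


def interval_ditype(tetrad: pd.Series | dict, marker_i: str = "m1", marker_j: str = "m2") -> str:
    """Ditype class of a single tetrad for one interval.

    Raises :class:`MalformedTetradError` when either marker is not
    present in exactly two of the four spores.
    """
    row = pd.DataFrame([tetrad])
    labels, valid = classify_intervals(row, marker_i, marker_j)
    if not valid[0]:
        tid = tetrad.get("tetrad_id", "?") if hasattr(tetrad, "get") else "?"
        raise MalformedTetradError(
            f"tetrad {tid}: markers {marker_i}/{marker_j} do not segregate 2:2"
        )
    return str(labels.iloc[0])


def perkins_distance(
    tetrads: pd.DataFrame,
    interval: tuple[str, str] = ("m1", "m2"),
    label: str | None = None,
) -> DistanceResult:
    """Perkins map distance cM = 100*(TT/2 + 3*NPD)/n over classifiable tetrads.

    Malformed tetrads (non-2:2 segregation) are excluded and counted in
    ``n_malformed``.
    """
    if len(tetrads) == 0:
        raise ValueError("no tetrads supplied")
    labels, valid = classify_intervals(tetrads, *interval)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no classifiable tetrads (all malformed)")
    n_pd = int((labels == PD).sum())
    n_tt = int((labels == TT).sum())
    n_npd = int((labels == NPD).sum())
    cm = 100.0 * (n_tt / 2.0 + 3.0 * n_npd) / n
    return DistanceResult(
        interval=label or f"{interval[0]}-{interval[1]}",
        n=n,
        pd=n_pd,
        tt=n_tt,
        npd=n_npd,
        cM=cm,
        n_malformed=int(len(tetrads) - n),
    )


def interference_ratio(
    tetrads: pd.DataFrame,
    focal_interval: tuple[str, str] = ("m2", "m3"),
    adjacent_interval: tuple[str, str] = ("m1", "m2"),
) -> InterferenceResult:
    """Interference ratio of the focal interval given the adjacent one.

    Tetrads are partitioned by the adjacent interval's class (PD: no
    crossover; TT or NPD: crossover — NPD is a subgroup label, not a
    weight) and the focal Perkins distance is computed inside each
    subgroup.  IFR = cM(focal | adjacent CO) / cM(focal | adjacent no
    CO), so interference gives IFR < 1 and clustering IFR > 1.  Tetrads
    malformed in either interval are excluded.
    """
    adj_labels, adj_valid = classify_intervals(tetrads, *adjacent_interval)
    _, foc_valid = classify_intervals(tetrads, *focal_interval)
    usable = adj_valid & foc_valid
    with_co = usable & (adj_labels != PD).to_numpy(dtype=bool)
    without_co = usable & (adj_labels == PD).to_numpy(dtype=bool)
    foc_name = f"{focal_interval[0]}-{focal_interval[1]}"
    adj_name = f"{adjacent_interval[0]}-{adjacent_interval[1]}"
    if not with_co.any() or not without_co.any():
        raise UndefinedRatioError(
            f"interference ratio {foc_name}|{adj_name}: empty subgroup"
        )
    res_with = perkins_distance(
        tetrads[with_co], focal_interval, label=f"{foc_name}|{adj_name}=CO"
    )
    res_without = perkins_distance(
        tetrads[without_co], focal_interval, label=f"{foc_name}|{adj_name}=noCO"
    )
    if res_without.cM == 0.0:
        raise UndefinedRatioError(
            f"interference ratio {foc_name}|{adj_name}: zero distance in the no-CO subgroup"
        )
    return InterferenceResult(
        focal=foc_name,
        adjacent=adj_name,
        with_adjacent_co=res_with,
        without_adjacent_co=res_without,
        ifr=res_with.cM / res_without.cM,
    )


def tetrad_event_spectrum(
    tetrads: pd.DataFrame,
    intervals: Sequence[tuple[str, str]] = (("m1", "m2"), ("m2", "m3")),
) -> dict[str, int]:
    """Histogram of crossover events per tetrad over the given intervals.

    Per tetrad and interval, PD contributes 0 events, TT 1 and NPD 2;
    tetrads malformed in any interval are excluded and reported under
    ``"malformed"``.  Event totals of three or more share the ``"3+"``
    class.
    """
    events = np.zeros(len(tetrads), dtype=int)
    all_valid = np.ones(len(tetrads), dtype=bool)
    for interval in intervals:
        labels, valid = classify_intervals(tetrads, *interval)
        all_valid &= valid
        events += np.select(
            [labels == TT, labels == NPD], [1, 2], default=0
        )
    spectrum = {
        "0": int(((events == 0) & all_valid).sum()),
        "1": int(((events == 1) & all_valid).sum()),
        "2": int(((events == 2) & all_valid).sum()),
        "3+": int(((events >= 3) & all_valid).sum()),
        "malformed": int((~all_valid).sum()),
    }
    return spectrum


def single_pollen_distance(pollen: pd.DataFrame) -> PollenDistance:
    """Map distance from single-pollen records: cM = 100 * recombinants / n.

    A pollen grain is recombinant when it carries exactly one of the two
    flanking markers (columns ``mA``, ``mB``).
    """
    if len(pollen) == 0:
        raise ValueError("no pollen records supplied")
    a = pollen["mA"].to_numpy(dtype=bool)
    b = pollen["mB"].to_numpy(dtype=bool)
    rec = int((a ^ b).sum())
    n = len(pollen)
    return PollenDistance(n=n, recombinant=rec, cM=100.0 * rec / n)


def fisher_recombination_test(rec1: int, tot1: int, rec2: int, tot2: int) -> float:
    """Two-sided Fisher exact p-value comparing two recombinant fractions.

    Tests the 2x2 table [[rec1, tot1-rec1], [rec2, tot2-rec2]] by
    summation of tables (with the observed margins) whose point
    probability does not exceed the observed one.
    """
    for v in (rec1, tot1, rec2, tot2):
        if int(v) != v or v < 0:
            raise ValueError("counts must be non-negative integers")
    if rec1 > tot1 or rec2 > tot2:
        raise ValueError("recombinant count exceeds total")
    table = [[rec1, tot1 - rec1], [rec2, tot2 - rec2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
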