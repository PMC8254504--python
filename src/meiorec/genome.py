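"""Genome model for BC1 crossover simulation and summary statistics.

A :class:`GenomeModel` carries, per chromosome, the physical length, the
genetic length of the transmitted (male) map, the centromere position and
optionally the informative-SNP positions.  Informative SNPs are the
"homozygous unique" sites: homozygous for different alleles in the two
parental accessions (Col-0 and Ws) and heterozygous in the F1 hybrid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Chromosome", "GenomeModel", "arabidopsis_like_genome", "load_genome"]


@dataclass
class Chromosome:
    name: str
    length_bp: int
    genetic_length_cM: float
    centromere_bp: int
    snp_positions_bp: np.ndarray | None = None  # sorted, strictly increasing, 1-based

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be positive")
        if self.genetic_length_cM < 0:
            raise ValueError(f"{self.name}: genetic_length_cM must be >= 0")
        if not (1 <= self.centromere_bp <= self.length_bp):
            raise ValueError(f"{self.name}: centromere outside chromosome")
        if self.snp_positions_bp is not None:
            pos = np.asarray(self.snp_positions_bp, dtype=np.int64)
            if pos.size and (pos[0] < 1 or pos[-1] > self.length_bp):
                raise ValueError(f"{self.name}: SNP positions outside [1, length_bp]")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{self.name}: SNP positions not strictly increasing")
            self.snp_positions_bp = pos

    @property
    def n_snps(self) -> int:
        return 0 if self.snp_positions_bp is None else int(self.snp_positions_bp.size)


@dataclass
class GenomeModel:
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_genetic_length_cM(self) -> float:
        return float(sum(c.genetic_length_cM for c in self.chromosomes))

    @property
    def total_snps(self) -> int:
        return sum(c.n_snps for c in self.chromosomes)


# Physical lengths and approximate centromere midpoints of the five
# A. thaliana chromosomes (TAIR10).  Genetic lengths are scaled so the map
# totals 520 cM, i.e. an expectation of 5.2 crossovers per transmitted
# gamete, matching the wild-type genome-wide estimate.
_ARABIDOPSIS = [
    # name, length_bp, centromere_bp, genetic_length_cM
    ("Chr1", 30_427_671, 15_086_045, 133.0),
    ("Chr2", 19_698_289, 3_607_930, 86.0),
    ("Chr3", 23_459_830, 13_799_418, 102.0),
    ("Chr4", 18_585_056, 3_956_021, 81.0),
    ("Chr5", 26_975_502, 11_725_024, 118.0),
]


def arabidopsis_like_genome(
    n_snps: int = 20_000,
    rng: np.random.Generator | None = None,
) -> GenomeModel:
    """Five-chromosome genome with ``n_snps`` informative sites in total.

    SNP counts are apportioned to chromosomes in proportion to physical
    length and positions drawn uniformly, emulating a dense genome-wide
    marker set at reduced scale.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lengths = np.array([c[1] for c in _ARABIDOPSIS], dtype=float)
    n_per = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    n_per[-1] += n_snps - n_per.sum()  # keep exact total
    chroms = []
    for (name, length, cen, cm), k in zip(_ARABIDOPSIS, n_per):
        pos = _sample_distinct_positions(int(k), int(length), rng)
        chroms.append(Chromosome(name, length, cm, cen, pos))
    return GenomeModel(chroms)


def _sample_distinct_positions(k: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` distinct 1-based positions uniformly on [1, length]."""
    if k > length:
        raise ValueError("more SNPs requested than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=int(k * 1.05) + 16))
    while pos.size < k:  # top up after collisions (rare at study densities)
        extra = rng.integers(1, length + 1, size=k)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=k, replace=False))


def load_genome(path: str | Path) -> GenomeModel:
    """Read a genome description from TOML or JSON.

    Expected structure::

        [[chromosomes]]
        name = "Chr1"
        length_bp = 30427671
        genetic_length_cM = 133.0
        centromere_bp = 15086045

    SNP positions are optional (``snp_positions_bp`` list).
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    chroms = []
    for c in data["chromosomes"]:
        pos = c.get("snp_positions_bp")
        chroms.append(
            Chromosome(
                name=str(c["name"]),
                length_bp=int(c["length_bp"]),
                genetic_length_cM=float(c["genetic_length_cM"]),
                centromere_bp=int(c["centromere_bp"]),
                snp_positions_bp=None if pos is None else np.asarray(pos, dtype=np.int64),
            )
        )
    return GenomeModel(chroms)


def save_genome(genome: GenomeModel, path: str | Path, include_snps: bool = True) -> None:
    """Write a genome description as JSON (the format ``load_genome`` reads)."""
    out = {"chromosomes": []}
    for c in genome:
        rec = {
            "name": c.name,
            "length_bp": int(c.length_bp),
            "genetic_length_cM": float(c.genetic_length_cM),
            "centromere_bp": int(c.centromere_bp),
        }
        if include_snps and c.snp_positions_bp is not None:
            rec["snp_positions_bp"] = [int(p) for p in c.snp_positions_bp]
        out["chromosomes"].append(rec)
    Path(path).write_text(json.dumps(out))
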