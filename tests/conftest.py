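"""Shared fixtures: seeded RNGs, a reduced genome, and builders for
programmatically generated tetrad / pollen / image fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from meiorec import arabidopsis_like_genome

# Spore marker-presence patterns realising each joint (interval-1, interval-2)
# ditype class for three coupled hemizygous markers m1-m2-m3.
_JOINT_PATTERNS = {
    ("PD", "PD"): [(1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0)],
    ("TT", "PD"): [(1, 0, 0), (1, 1, 1), (0, 1, 1), (0, 0, 0)],
    ("PD", "TT"): [(1, 1, 0), (1, 1, 1), (0, 0, 1), (0, 0, 0)],
    ("TT", "TT"): [(1, 0, 1), (1, 1, 1), (0, 1, 0), (0, 0, 0)],
}


def build_tetrad_table(joint_counts: dict[tuple[str, str], int], seed: int = 0) -> pd.DataFrame:
    """Synthetic tetrad table with prescribed joint ditype counts.

    ``joint_counts`` maps (interval-1 class, interval-2 class) to the
    number of tetrads of that joint class; rows are shuffled
    deterministically so classification order carries no signal.
    """
    rows = []
    for joint, count in joint_counts.items():
        pattern = _JOINT_PATTERNS[joint]
        for _ in range(count):
            rows.append([v for spore in pattern for v in spore])
    rng = np.random.default_rng(seed)
    rows = [rows[i] for i in rng.permutation(len(rows))]
    cols = [f"s{s}_m{m}" for s in (1, 2, 3, 4) for m in (1, 2, 3)]
    df = pd.DataFrame(rows, columns=cols).astype(bool)
    df.insert(0, "tetrad_id", np.arange(1, len(df) + 1))
    return df


def build_pollen_table(n_recombinant: int, n_total: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic single-pollen table with a prescribed recombinant count.

    Non-recombinants split evenly between both-marker and no-marker
    pollen; recombinants alternate between the two single-marker states.
    """
    rows = []
    for i in range(n_recombinant):
        rows.append((True, False) if i % 2 == 0 else (False, True))
    n_par = n_total - n_recombinant
    for i in range(n_par):
        rows.append((True, True) if i % 2 == 0 else (False, False))
    rng = np.random.default_rng(seed)
    rows = [rows[i] for i in rng.permutation(len(rows))]
    df = pd.DataFrame(rows, columns=["mA", "mB"])
    df.insert(0, "pollen_id", np.arange(1, len(df) + 1))
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_genome():
    """Five-chromosome genome with 20,000 informative SNPs (fixed layout)."""
    return arabidopsis_like_genome(n_snps=20_000, rng=np.random.default_rng(11))
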