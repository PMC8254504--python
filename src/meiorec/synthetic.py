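"""Ground-truth simulators for every input the analysis pipeline consumes.

Four generators are provided:

* an interfering crossover process on the transmitted gamete (stationary
  gamma renewal with shape ``nu``; ``nu = 1`` is the non-interfering
  Poisson case), giving BC1 zygosity mosaics with known breakpoints;
* a low-coverage sequencing emulator producing per-SNP allele read
  counts (Poisson depth, allele-call error);
* a two-interval tetrad simulator for fluorescent-tagged-line assays
  (Bernoulli chiasma per interval with a coincidence parameter ``S``,
  chromatids chosen without chromatid interference), plus expansion of
  tetrads into single-pollen records;
* a single-molecule spot-image renderer (isotropic Gaussian peaks on a
  constant background with Gaussian noise, 16-bit range) with recorded
  true centers.

Crossovers are simulated directly on the transmitted chromatid at rate
L/100 Morgans rather than on a four-chromatid bivalent with thinning:
the downstream caller only ever sees the gamete, and the marginal CO
rate is the same; ``nu`` is therefore a gamete-level interference knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .caller import AlleleCounts
from .genome import Chromosome, GenomeModel

__all__ = [
    "SimParams",
    "MeiosisTruth",
    "SpotGroundTruth",
    "PlacementError",
    "simulate_crossovers",
    "simulate_meiosis",
    "zygosity_at",
    "simulate_backcross_counts",
    "simulate_tetrads",
    "tetrads_to_pollen",
    "render_spot_image",
]

MORGAN_CM = 100.0  # mean inter-crossover distance along the gamete, in cM


@dataclass
class SimParams:
    """Simulator knobs for the BC1 sequencing emulator.

    coverage_mean
        Poisson mean read depth per SNP (λ).  Default 3.0, inside the
        1.0–8.7x range of the emulated screen.
    error_rate
        Per-read probability ε that the called allele is flipped.
        Default 0.005.
    interference_shape
        Gamma renewal shape ν ≥ 1 of the crossover process; ν = 1 is a
        Poisson (no-interference) process.  Default 5.0, a typical
        strength for plant class I crossover interference.
    coincidence
        Coincidence S ∈ [0, ∞) of the two-interval tetrad model
        (S < 1: interference; S = 1: independence).  Default 0.3,
        matching wild-type interference ratios of ~0.2–0.4.
    """

    coverage_mean: float = 3.0
    error_rate: float = 0.005
    interference_shape: float = 5.0
    coincidence: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")
        if not (0.0 <= self.error_rate <= 0.5):
            raise ValueError("error_rate must be in [0, 0.5]")
        if self.interference_shape < 1:
            raise ValueError("interference_shape must be >= 1")
        if self.coincidence < 0:
            raise ValueError("coincidence must be >= 0")


@dataclass
class MeiosisTruth:
    """Simulated crossover positions and start phase of one BC1 genome.

    ``co_positions_bp[chrom]`` is the sorted list of crossover positions
    on the transmitted F1 chromatid; ``start_phase[chrom]`` is the BC1
    offspring zygosity ('HET' or 'HOM_COL') at position 1.  Zygosity at
    any locus is the start phase flipped once per crossover to its left.
    """

    co_positions_bp: dict[str, np.ndarray] = field(default_factory=dict)
    start_phase: dict[str, str] = field(default_factory=dict)

    def n_cos(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(len(self.co_positions_bp[chrom]))
        return int(sum(len(v) for v in self.co_positions_bp.values()))


@dataclass
class SpotGroundTruth:
    image: np.ndarray  # uint16
    true_centers: np.ndarray  # (n, 2) float rows (row, col)
    amplitude: float
    background: float
    noise_sd: float


class PlacementError(RuntimeError):
    """Raised when non-overlapping spot placement fails after bounded retries."""


# ---------------------------------------------------------------------------
# Crossover process
# ---------------------------------------------------------------------------


def _equilibrium_first_arrival(nu: float, rng: np.random.Generator) -> float:
    """Draw the distance to the first event of a stationary gamma renewal
    process with mean inter-event distance MORGAN_CM and shape ``nu``.

    The equilibrium (forward recurrence) CDF is
    F_e(x) = [x·S(x; ν) + μ·F(x; ν+1)] / μ with scale μ/ν; it is inverted
    numerically.  For ν = 1 this reduces to the exponential.
    """
    mu = MORGAN_CM
    if nu == 1.0:  # equilibrium of the exponential is the exponential itself
        return float(rng.exponential(mu))
    scale = mu / nu
    u = rng.random()

    def cdf(x: float) -> float:
        z = x / scale
        return (x * (1.0 - special.gammainc(nu, z)) + mu * special.gammainc(nu + 1.0, z)) / mu

    hi = mu
    while cdf(hi) < u:
        hi *= 2.0
    return float(optimize.brentq(lambda x: cdf(x) - u, 0.0, hi, xtol=1e-9))


def simulate_crossovers(
    genetic_length_cM: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Crossover positions (cM) on one gamete, sorted.

    A stationary gamma renewal point process on [0, L] with shape ``nu``
    and mean inter-event distance 100 cM, so the expected event count is
    L/100.  The first event comes from the equilibrium inter-arrival
    distribution; subsequent gaps are Gamma(ν, 100/ν).
    """
    if genetic_length_cM < 0:
        raise ValueError("genetic length must be >= 0")
    if nu < 1:
        raise ValueError("interference shape nu must be >= 1")
    L = float(genetic_length_cM)
    if L == 0.0:
        return np.empty(0, dtype=float)
    out: list[float] = []
    x = _equilibrium_first_arrival(nu, rng)
    while x < L:
        out.append(x)
        x += rng.gamma(nu, MORGAN_CM / nu)
    return np.asarray(out, dtype=float)


def simulate_meiosis(
    genome: GenomeModel, params: SimParams, rng: np.random.Generator
) -> MeiosisTruth:
    """One F1 meiosis: crossovers on every chromosome plus the start phase.

    cM positions are mapped to bp linearly (uniform recombination
    density along the chromosome); the transmitted chromatid starts in
    either phase with probability 1/2.
    """
    truth = MeiosisTruth()
    for chrom in genome:
        pos_cm = simulate_crossovers(chrom.genetic_length_cM, params.interference_shape, rng)
        if chrom.genetic_length_cM > 0:
            pos_bp = np.ceil(pos_cm / chrom.genetic_length_cM * chrom.length_bp).astype(np.int64)
            pos_bp = np.clip(pos_bp, 1, chrom.length_bp)
        else:
            pos_bp = np.empty(0, dtype=np.int64)
        truth.co_positions_bp[chrom.name] = pos_bp
        truth.start_phase[chrom.name] = "HET" if rng.random() < 0.5 else "HOM_COL"
    return truth


def zygosity_at(truth: MeiosisTruth, chrom: str, pos_bp: int) -> str:
    """Zygosity ('HET' or 'HOM_COL') of the BC1 offspring at one locus."""
    if chrom not in truth.co_positions_bp:
        raise KeyError(f"unknown chromosome {chrom!r}")
    n_left = int(np.searchsorted(truth.co_positions_bp[chrom], pos_bp, side="left"))
    phase = truth.start_phase[chrom]
    if n_left % 2 == 1:
        phase = "HOM_COL" if phase == "HET" else "HET"
    return phase


# ---------------------------------------------------------------------------
# Low-coverage sequencing emulator
# ---------------------------------------------------------------------------


def simulate_backcross_counts(
    truth: MeiosisTruth,
    genome: GenomeModel,
    params: SimParams,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> AlleleCounts:
    """Per-SNP allele read counts for one BC1 individual.

    Depth per SNP is Poisson(λ).  At heterozygous sites each read
    supports Col-0 with probability 1/2, at homozygous-Col sites with
    probability 1; each read's called allele is then flipped with
    probability ε.  R counts Col-0 (reference) reads, A counts Ws
    (alternative) reads, so R + A equals the drawn depth at every site.
    """
    frames = []
    eps = params.error_rate
    for chrom in genome:
        pos = chrom.snp_positions_bp
        if pos is None or pos.size == 0:
            continue
        cos = truth.co_positions_bp[chrom.name]
        n_left = np.searchsorted(cos, pos, side="left")
        het = n_left % 2 == (0 if truth.start_phase[chrom.name] == "HET" else 1)
        depth = rng.poisson(params.coverage_mean, size=pos.size)
        p_col_true = np.where(het, 0.5, 1.0)
        p_col = p_col_true * (1.0 - eps) + (1.0 - p_col_true) * eps
        R = rng.binomial(depth, p_col)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom.name, "pos": pos, "ref": R, "alt": depth - R}
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    return AlleleCounts(table=table, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Tetrad / pollen simulator
# ---------------------------------------------------------------------------

SPORE_MARKER_COLUMNS = [f"s{s}_m{m}" for s in (1, 2, 3, 4) for m in (1, 2, 3)]


def simulate_tetrads(
    d1_cM: float,
    d2_cM: float,
    S: float,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate ``n`` pollen tetrads for two adjacent marked intervals.

    Three coupled hemizygous fluorescent markers m1–m2–m3 delimit
    interval 1 (m1–m2, map length ``d1_cM``) and interval 2 (m2–m3,
    ``d2_cM``).  Each meiosis draws at most one chiasma per interval,
    with marginal probabilities d_i/50 and joint probability
    S·(d1/50)·(d2/50); each chiasma exchanges the distal segment between
    one chromatid carrying the interval's proximal marker and one not,
    chosen uniformly and independently per interval (no chromatid
    interference).  Crossovers are thus modelled at the level of the
    *visible* exchange — every chiasma yields a tetratype for its
    interval — so S is the coincidence of visible crossovers, which is
    what the assay measures, and the interference ratio tends to S as
    the intervals shrink.  Within-interval double chiasmata are
    neglected, which is adequate for intervals of a few cM; simulated
    tetrads therefore contain no NPDs, though the analysis code accepts
    them.

    Returns a table with one row per tetrad: ``tetrad_id`` and boolean
    marker presence ``s{1..4}_m{1..3}``.
    """
    if not (0.0 <= d1_cM < 50.0 and 0.0 <= d2_cM < 50.0):
        raise ValueError("interval distances must be in [0, 50) cM")
    if S < 0:
        raise ValueError("coincidence S must be >= 0")
    p1, p2 = d1_cM / 50.0, d2_cM / 50.0
    p11 = S * p1 * p2
    if p11 > min(p1, p2) + 1e-12:
        raise ValueError("joint chiasma probability exceeds a marginal")
    p10, p01 = p1 - p11, p2 - p11
    p00 = 1.0 - p10 - p01 - p11
    if p00 < -1e-12:
        raise ValueError("infeasible joint chiasma probability")
    probs = np.clip([p00, p10, p01, p11], 0.0, 1.0)
    probs = probs / probs.sum()
    cat = rng.choice(4, size=n, p=probs)  # 0 none, 1 ivl1, 2 ivl2, 3 both
    has1 = (cat == 1) | (cat == 3)
    has2 = (cat == 2) | (cat == 3)
    # chromatids 0,1 carry all three markers; 2,3 carry none
    M = np.zeros((n, 4, 3), dtype=bool)
    M[:, :2, :] = True
    # strand choices are drawn for every meiosis to keep the RNG stream
    # independent of the chiasma outcome
    a1 = rng.integers(0, 2, size=n)
    b1 = rng.integers(2, 4, size=n)
    u2 = rng.integers(0, 2, size=n)
    w2 = rng.integers(0, 2, size=n)
    idx = np.flatnonzero(has1)  # exchange distal to m1: markers m2, m3
    tmp = M[idx, a1[idx], 1:].copy()
    M[idx, a1[idx], 1:] = M[idx, b1[idx], 1:]
    M[idx, b1[idx], 1:] = tmp
    # interval-2 exchange: one chromatid carrying m2, one not (uniform),
    # swapping the segment distal to m2 (marker m3)
    idx = np.flatnonzero(has2)
    order = np.argsort(~M[idx, :, 1], axis=1, kind="stable")  # m2 carriers first
    a2 = order[np.arange(idx.size), u2[idx]]
    b2 = order[np.arange(idx.size), 2 + w2[idx]]
    tmp = M[idx, a2, 2].copy()
    M[idx, a2, 2] = M[idx, b2, 2]
    M[idx, b2, 2] = tmp
    data = {"tetrad_id": np.arange(1, n + 1)}
    for s in range(4):
        for m in range(3):
            data[f"s{s + 1}_m{m + 1}"] = M[:, s, m]
    return pd.DataFrame(data)


def tetrads_to_pollen(
    tetrads: pd.DataFrame, markers: tuple[str, str] = ("m1", "m2")
) -> pd.DataFrame:
    """Expand each tetrad into its four single-pollen records.

    Each pollen record reports presence of the two markers flanking the
    focal interval (columns ``mA``, ``mB``); single-marker pollen are the
    recombinants counted by the single-pollen assay.
    """
    mA, mB = markers
    rows = []
    for s in (1, 2, 3, 4):
        sub = pd.DataFrame(
            {
                "tetrad_id": tetrads["tetrad_id"],
                "spore": s,
                "mA": tetrads[f"s{s}_{mA}"].to_numpy(),
                "mB": tetrads[f"s{s}_{mB}"].to_numpy(),
            }
        )
        rows.append(sub)
    pollen = pd.concat(rows, ignore_index=True)
    pollen = pollen.sort_values(["tetrad_id", "spore"], kind="stable").reset_index(drop=True)
    pollen.insert(0, "pollen_id", np.arange(1, len(pollen) + 1))
    return pollen[["pollen_id", "mA", "mB"]]


# ---------------------------------------------------------------------------
# Spot image renderer
# ---------------------------------------------------------------------------


def render_spot_image(
    shape: tuple[int, int] = (256, 256),
    n_spots: int = 50,
    amplitude: float = 10_000.0,
    sigma_px: float = 2.0,
    background: float = 500.0,
    noise_sd: float = 100.0,
    border_margin_px: int | None = None,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
    max_tries: int = 20_000,
) -> SpotGroundTruth:
    """Render a 16-bit single-molecule image with known spot centers.

    The image is a constant ``background`` plus ``n_spots`` isotropic
    Gaussian peaks of height ``amplitude`` and width ``sigma_px``, plus
    Gaussian noise, rounded and clipped to [0, 65535].  Random centers
    keep a mutual distance of at least 6·sigma and stay
    ``border_margin_px`` away from the edges (default ceil(3·sigma)+2);
    pass explicit ``centers`` to place spots anywhere, e.g. on the
    border for border-exclusion tests.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nrow, ncol = shape
    if amplitude + background > 65535:
        raise ValueError("amplitude + background exceeds the 16-bit range")
    if border_margin_px is None:
        border_margin_px = int(np.ceil(3 * sigma_px)) + 2
    min_sep = 6.0 * sigma_px
    if centers is None:
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < n_spots:
            if tries >= max_tries:
                raise PlacementError(
                    f"could not place {n_spots} spots with separation {min_sep:.1f} px"
                )
            tries += 1
            r = rng.uniform(border_margin_px, nrow - 1 - border_margin_px)
            c = rng.uniform(border_margin_px, ncol - 1 - border_margin_px)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
                placed.append((r, c))
        centers = np.asarray(placed, dtype=float).reshape(-1, 2)
    else:
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        if centers.size and (
            centers[:, 0].min() < 0
            or centers[:, 1].min() < 0
            or centers[:, 0].max() > nrow - 1
            or centers[:, 1].max() > ncol - 1
        ):
            raise ValueError("explicit centers must lie inside the image")
    img = np.full(shape, float(background))
    win = int(np.ceil(5 * sigma_px))
    for r, c in centers:
        r0 = max(0, int(np.floor(r)) - win)
        r1 = min(nrow, int(np.ceil(r)) + win + 1)
        c0 = max(0, int(np.floor(c)) - win)
        c1 = min(ncol, int(np.ceil(c)) + win + 1)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * sigma_px**2)
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return SpotGroundTruth(
        image=img,
        true_centers=centers,
        amplitude=float(amplitude),
        background=float(background),
        noise_sd=float(noise_sd),
    )
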