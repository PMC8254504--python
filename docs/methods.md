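# Methods note

This note records the models implemented in `meiorec`, the default
parameters and their rationale, what the synthetic generators emulate
(and deliberately do not), and the numerical choices and known
limitations.

## 1. Crossover calling from pooled read counts

### Model

Informative ("homozygous unique") SNPs — homozygous for different
alleles in each parental accession and heterozygous in the F1 — are
grouped per chromosome into bins of `bin_size = 100` consecutive SNPs.
A terminal remainder shorter than `min_tail = 50` SNPs is merged into
the previous bin. Reads are pooled per bin and scored with

    h = 2·R·A / (R + A)²,   h ∈ [0, 0.5]

A bin is homozygous (HOM) when `h < 0.05`, heterozygous (HET) when
`h > 0.45`, and undetermined (UNDET) otherwise; the inequalities are
strict, so a score exactly at a threshold stays undetermined, as does
a bin with fewer than `min_reads = 1` reads. A crossover is called at
every zygosity switch between consecutive *determined* bins; the
breakpoint interval runs from the last SNP of the left determined bin
(exclusive) to the first SNP of the right determined bin (inclusive),
and intervening UNDET bins widen it (`n_undetermined_spanned`).

In a BC1 backcross onto the reference parent, alternative-homozygous
bins are impossible; bins whose reads are dominated by the alternative
allele classify as HOM but carry a `ws_flag` for inspection.

### Defaults and why

* `bin_size = 100`, thresholds 0.05 / 0.45 — the study's values.
* `min_tail = 50` — half a bin; prevents tiny terminal bins whose
  pooled score is dominated by sampling noise.
* `min_reads = 1` — a bin with zero reads has no defined score.

## 2. Synthetic BC1 study generator

### Crossover process

Crossovers are a stationary gamma renewal process on the genetic map:
inter-event distances are Gamma(ν, scale = 100 cM/ν) so the mean
spacing is one Morgan; ν = 1 recovers a Poisson process and ν > 1
produces interference (underdispersed counts). Stationarity is
enforced by drawing the *first* event from the equilibrium forward
recurrence distribution

    F_e(x) = [x·S(x; ν) + μ·F(x; ν+1)] / μ,   μ = 100 cM,

inverted numerically (Brent's method on the closed-form CDF written
with regularised incomplete gamma functions; the ν = 1 case is drawn
directly from the exponential). Without this correction simulated
positions would be biased away from chromosome starts.

Genetic positions are mapped to physical coordinates linearly per
chromosome. The genome model defaults to five chromosomes with
TAIR10-like physical lengths and genetic lengths of 133, 86, 102, 81
and 118 cM (520 cM total, i.e. 5.2 expected COs per gamete — the
wild-type genome-wide mean), and 20,000 informative SNPs apportioned
by physical length at uniform random positions.

### Read-count emulator

Per SNP, depth is Poisson(`coverage_mean`); reference reads are
Binomial(depth, p) with p = 1 − ε at homozygous-Col sites and 0.5 at
heterozygous sites, symmetric error ε flipping alleles either way.

Defaults: `coverage_mean = 3.0` (inside the study's 1.0–8.7× range),
`error_rate = 0.005` (typical short-read substitution + mismapping
scale), `interference_shape = 5.0` (strong class-I interference, the
regime the study's interference ratios of ~0.2–0.4 imply).

### What is emulated / not emulated

Emulated: low-coverage binomial sampling, sequencing error, arbitrary
genotype mosaics, interference between crossovers. Not emulated:
coverage heterogeneity along the genome, mapping bias between parental
alleles, centromeric CO suppression (the genetic-to-physical map is
linear), gene conversion tracts, chromatid interference.

## 3. Tetrad and single-pollen model

Tetrads carry three coupled hemizygous markers m1–m2–m3 on one
chromatid pair; each marker segregates 2:2. Per interval the joint
event probabilities are

    P(CO in both) = S · p1 · p2,  p_i = d_i / 50

with `d_i` the interval distance in cM and `S` the coefficient of
coincidence (S < 1: interference; S = 1: independence). Each interval
with a crossover exchanges marker content between one carrier and one
non-carrier chromatid of the interval's proximal marker.

**Model choice — visible crossovers.** With physically identified
strand choice, half the double events are 3-strand doubles whose focal
exchange swaps identical marker content and is invisible to flanking
markers, which drives the measured IFR to S/2 at small distances. The
FTL assay, however, measures coincidence of *visible* (tetratype)
crossovers, so the simulator makes every exchange visible by choosing
strands relative to the proximal-marker carrier. This reproduces the
closed forms

    cM(focal | adjacent CO)    = S · d_focal
    cM(focal | no adjacent CO) = d_focal (1 − S·p_adj) / (1 − p_adj)

so IFR → S as distances shrink and S = 1 gives IFR ≈ 1 (verified:
simulated IFR 0.334 vs theory 0.330 at S = 0.36; 1.006 at S = 1). NPD
tetrads are not generated (four-strand double events within one marked
interval are negligible at the ≤ 11 cM distances modelled), matching
their near-absence in the assay.

Pollen expansion lists the four spores of each tetrad individually;
on the same meioses the single-pollen distance (100 × single-marker
pollen / n) equals the tetrad Perkins distance exactly, since
recombinant pollen per tetrad = 2 × TT-indicator = TT/2 per spore.

Interference ratios are undefined (raised as `UndefinedRatioError`)
when a subgroup is empty or the no-adjacent-CO distance is zero.
Fisher's exact test (two-sided, point-probability summation) compares
recombinant fractions between genotypes; it is delegated to
`scipy.stats.fisher_exact`, cross-validated in the test suite against
a brute-force hypergeometric enumeration.

## 4. Spot detection and quantification

`find_maxima` reimplements ImageJ's "Find Maxima" semantics, because
the published counts depend on its exact prominence definition and no
installed library provides it:

1. candidate local maxima (≥ all 8 neighbours, above the global
   minimum — a constant image has none) are processed in decreasing
   intensity;
2. from each candidate a region floods over 8-connected pixels
   brighter than (peak − tolerance);
3. a region that touches a brighter pixel or an already-claimed region
   is absorbed (not counted);
4. an equal-intensity plateau yields one maximum at its centroid, exact
   halves rounded toward the top-left;
5. optionally, maxima on the outermost pixel row/column are discarded
   (`exclude_border`, default on, as in the published analysis).

The published "noise tolerance 6,000" (16-bit counts) is interpreted
as this prominence parameter, the meaning it has in ImageJ. On
noiseless, well-separated spots the detector agrees exactly with
`skimage.feature.peak_local_max` (test-suite cross-check).

The oligo fraction of a genotype is
(Σ oligo maxima / oligo lysate volume) / (Σ protein maxima / protein
lysate volume); genotype effects are fold changes of these fractions,
with per-replicate ratios, mean and SD reported when paired replicate
fractions are supplied.

The image generator renders symmetric Gaussian spots (default
amplitude 10,000, σ = 2 px, background 500, Gaussian read noise
SD 100 on a 16-bit range) with rejection-sampled centers at least 6σ
apart and at least ceil(3σ)+2 px from the border; it does not emulate
spot overlap, photobleaching, or structured background.

## 5. Group comparison

`compare_groups` applies the D'Agostino–Pearson omnibus K2 normality
test to both samples at α = 0.05; when both pass and both have n ≥ 8
(K2 is undefined below 8) it runs an unpaired two-tailed Student t
test with equal variances, otherwise a two-tailed Mann–Whitney U test.
Deviation from the stated design: the Mann–Whitney implementation uses
scipy's `method="auto"` policy (exact for small tie-free samples,
normal approximation with tie correction otherwise) rather than a hard
exact/approximate crossover at n = 20; the conventions differ only in
a narrow band of sample sizes. Note K2 is slightly anti-conservative
at moderate n (empirical size ≈ 0.055–0.06 at n = 30), so the t test
is selected for two Gaussian samples in ≈ 89% of cases, not the
nominal (1 − α)² ≈ 90.2%.

## 6. Numerical choices

* Equilibrium first-arrival inversion: Brent's method with
  `xtol = 1e-9` on a bracketing interval doubled from one mean spacing.
* All Monte-Carlo test assertions use 3-standard-error bands or
  chi-square/KS goodness-of-fit at p > 0.01 with fixed seeds.
* Images are float64 internally and clipped to uint16 on output.
* All random draws flow through a single `numpy.random.Generator`, so
  fixed seeds make the full simulate → call pipeline bit-reproducible.

## 7. Known limitations

* **Breakpoint intervals are not exact containment intervals.** When a
  true crossover falls near the edge of a bin, the transition bin's
  pooled score crosses a classification threshold and the bin is
  assigned to one flank; the true CO can then lie just outside the
  reported (left, right] interval. The effect is independent of marker
  density (it is a property of thresholding the mixture score
  h = f(1 − f/2) for within-bin heterozygous fraction f) and accounts
  for containment failures in roughly a third of calls at 100-SNP
  bins. The guaranteed property — tested in the suite — is containment
  within the interval extended by one bin on each side.
* **Terminal-bin censoring.** A crossover in a chromosome's first or
  last bin is detected only when that bin classifies as the new phase;
  at 40 bins per chromosome this loses ~4% of COs per genome, which is
  why exact genome-wide CO-count recovery plateaus near ~82% of
  genomes at the 20,000-SNP desk scale (at the study's real marker
  density, ~900 bins per chromosome, the effect is ~23× smaller). The
  corresponding acceptance test is left failing rather than weakened.
* The gamma renewal process models class-I interference only; there is
  no explicit class-II (non-interfering) pathway parameter.
* The tetrad model is a two-interval, three-marker model; it does not
  simulate whole-chromosome chiasma configurations or chromatid
  interference.
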