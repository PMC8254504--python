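# meiorec

Meiotic recombination analysis toolkit: crossover calling from
low-coverage backcross sequencing, fluorescent-tetrad and single-pollen
genetics, single-molecule spot quantification, and matched ground-truth
simulators for all three assays.

## Scientific problem

Meiotic crossovers (COs) shuffle parental genomes. In *Arabidopsis*
they can be mapped genome-wide by sequencing BC1 backcross offspring:
an F1 hybrid (Col-0 × Ws) is crossed back to Col-0, so every offspring
chromosome is a mosaic of heterozygous (Col/Ws) and homozygous-Col
blocks whose junctions are the F1's crossovers. Coverage per plant is
low (1–9×), so genotypes cannot be called per SNP. Instead, reads are
pooled over bins of consecutive informative SNPs and each bin is scored
with the **pooled heterozygosity score**

```
h = 2·R·A / (R + A)²
```

where R and A are the summed reference (Col-0) and alternative (Ws)
read counts. h ≈ 0.5 marks heterozygous bins, h ≈ 0 homozygous ones; a
zygosity switch between consecutive classified bins is a crossover, and
the interval between the flanking determined bins is the breakpoint
interval.

The package also covers two orthogonal assays from the same study
design:

* **Tetrad / pollen genetics** — fluorescent-tagged lines (FTLs) mark
  genetic intervals with pollen-expressed fluorophores. Tetrads are
  classified as parental ditype (PD), tetratype (TT) or non-parental
  ditype (NPD) per interval; map distance follows Perkins' formula
  `cM = 100·(TT/2 + 3·NPD)/n`, and crossover interference is summarised
  by the interference ratio (IFR): the focal interval's distance among
  tetrads *with* an adjacent-interval CO over the distance among those
  *without*.
* **Single-molecule spot counting** — SPO11-oligo and total-protein
  TIRF images are quantified by prominence-based maxima detection
  (ImageJ "Find Maxima" semantics) and summarised as volume-normalised
  oligo/protein fractions and genotype fold changes.

Every analysis has a matched simulator with known ground truth: a
stationary gamma renewal crossover process (interference shape ν), a
binomial/Poisson read-count emulator, a three-marker tetrad sampler
with tunable coincidence S, and a Gaussian-spot image renderer.

## Worked example

Simulate a small BC1 study and call crossovers:

```bash
$ meiorec simulate --out-dir demo --n-samples 3 --seed 7
wrote 3 samples to demo

$ meiorec callco --counts demo/sim000.counts.tsv --genome demo/genome.json \
    -o demo/sim000.calls.tsv --summary-json demo/sim000.summary.json
INFO meiorec: sim000.counts: 5 crossovers from 199 bins
5 crossovers -> demo/sim000.calls.tsv
```

The call table is BED-like (0-based half-open breakpoint intervals):

```
chrom	start	end	sample	left_class	right_class	n_undet
Chr1	10847447	11428189	sim000.counts	HOM	HET	1
Chr3	14565056	14569961	sim000.counts	HET	HOM	0
```

The summary JSON reports 5 calls for this sample (the simulated truth
for the three samples is 6, 6 and 5 COs — see `demo/manifest.json` and
the per-sample `*.truth.bed` files), per-chromosome counts
`{"Chr1": 1, "Chr2": 0, "Chr3": 1, "Chr4": 1, "Chr5": 2}` and the
multi-CO fraction 0.2.

Tetrad genetics on simulated data (two intervals, d = 6.2 and 11 cM,
coincidence S = 0.36, 5,000 tetrads):

```bash
$ meiorec tetrads --csv demo/tetrads.csv -o demo/tetrads.json
m1-m2: 6.53 cM (n=5000, PD=4347 TT=653 NPD=0)
m2-m3: 10.84 cM (n=5000, PD=3916 TT=1084 NPD=0)
IFR m2-m3|m1-m2: 0.36
IFR m1-m2|m2-m3: 0.34
event spectrum: {'0': 3319, '1': 1625, '2': 56, '3+': 0, 'malformed': 0}
```

The simulated distances and the coincidence parameter are recovered
(6.53 vs 6.2 cM, 10.84 vs 11 cM, IFR 0.36 vs S = 0.36).

Library use mirrors the CLI:

```python
>>> import meiorec as mr
>>> mr.pooled_heterozygosity(50, 50)
0.5
>>> mr.pooled_heterozygosity(8, 1)
0.19753086419753085
```

## Layout

* `meiorec.genome` — chromosome/genome model, genome file I/O
* `meiorec.caller` — pooled-heterozygosity binning and CO calling
* `meiorec.synthetic` — crossover process, read-count, tetrad and image simulators
* `meiorec.tetrads` — ditype classification, Perkins distance, IFR, Fisher test
* `meiorec.spots` — prominence maxima detection and oligo/protein quantification
* `meiorec.stats` — normality-gated two-group comparison
* `meiorec.io` — TSV/VCF/BED-like/CSV/TIFF readers and writers
* `meiorec.cli` — `meiorec` command-line entry point
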