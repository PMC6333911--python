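# breedsim

Stochastic, individual-plant, locus-level simulation of crop breeding
programs — for quantitative geneticists and breeding-program designers who
want to compare selection strategies (phenotypic selection, genomic
selection, optimum-contribution selection, speed breeding) before committing
field seasons to them.

The simulator traces every plant's phased bi-allelic genome through a
breeding program organized as *overlapping cycles*: a new cycle starts every
time step, and early generations of one cycle feed parents into the next
through stored germplasm, as in commercial line-breeding programs.

## The model in brief

* **Genome & founders.** Loci (QTLs and markers) sit on a Morgan-scaled map;
  meiosis uses Poisson crossovers (mean = map length) with no interference.
  Founder linkage disequilibrium is built by a Fisher-Wright process with
  mutation, drift and selection (the 5% of offspring with lowest breeding
  value are culled and resampled each generation). Phased genotypes can also
  be imported from a documented TSV dialect or phased VCF.
* **Traits.** True breeding value is additive over QTLs,
  `g_i = Σ_j x_ij a_j`; mutant effects are exponential with 90% negative
  sign (one trait) or multivariate normal over correlated traits, then
  standardized so the Hardy-Weinberg base variance equals `σ²_g` exactly.
  Phenotypes are `y = g + e`. Residual variance can be set from a *plot
  heritability* prior via the closed form
  `σ²_e = 2 Ns H σ²_g (1 − h²_plot)/h²_plot − (1 − H) σ²_g`
  (`Ns` plants per plot, `H` homozygosity; plots are scored as sums).
* **Prediction & selection.** Truncation or threshold selection on
  population / within-family / entire-family units; pedigree BLUP and
  genomic GBLUP (VanRaden G, multi-trait Henderson mixed-model equations);
  optimum-contribution selection maximizing
  `U(c) = c'â − (ω/L²)(c+Pv)'A(c+Pv)` on the simplex.
* **Engine.** Per-generation stages (phenotyping → EBV → selection →
  germplasm storage → propagation by selfing / crossing / cloning / doubled
  haploids) on a calendar of overlapping cycles; speed breeding compresses
  several generations into one time step; burn-in switching activates
  genomic selection mid-run. Everything is seed-reproducible.

Three wheat breeding plans ship as TOML configurations, at full published
scale and at a reduced test scale: **plan A** (phenotypic selection),
**plan B** (genomic selection after a 10-year burn-in) and **plan C**
(speed breeding + genomic selection). See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Genomic prediction beating single-record phenotypic ranking on simulated
inbred lines (`examples/gblup_vs_phenotype.py`):

```text
300 inbred lines, phenotype heritability 0.3
accuracy of phenotypic ranking:  0.535 (theory ~ sqrt(h2) = 0.548)
accuracy of GBLUP ranking:       0.761
```

The phenotype's accuracy matches its theoretical `√h²`; GBLUP exceeds it by
borrowing information across genomically related lines — the mechanism that
lets the genomic-selection plan act on yield three generations earlier than
the phenotypic plan.

Comparing the three shipped plans at reduced scale
(`examples/plan_comparison.py`, a few minutes):

```text
rate of genetic gain in YA, time steps (11, 25) (10 replicates):
   PS: 0.066 +- 0.067 per year; genetic variance left at horizon 1.32
   GS: 0.115 +- 0.061 per year; genetic variance left at horizon 0.91
  SPB: 0.186 +- 0.047 per year; genetic variance left at horizon 0.04
GS / PS ratio: 1.75
SPB / PS ratio: 2.83
```

Gains are in standardized genetic-variance units of the advanced-trial
yield trait per year, measured as the OLS slope of the released (F8) lines'
mean breeding value over the post-burn-in window. Speed breeding gains
fastest (improved parents recycle sooner), genomic selection beats
phenotypic selection, and phenotypic selection retains the most genetic
variance because its selection is least accurate; the per-plan slopes are
noisy at this replicate count because the reduced plan releases a single
line per year.

Other examples: `examples/founder_ld.py` (founder diversity and LD),
`examples/heritability_calibration.py` (plot-heritability calibration),
`examples/ocs_tradeoff.py` (merit-vs-inbreeding trade-off).

## Command line

```bash
breedsim simulate --config plan_a_small --seed 1 --replicates 3 --out results/
breedsim summarize --in results/
```

`--config` takes a TOML file or a builtin name (`plan_a`, `plan_b`,
`plan_c`, and their `_small` reduced-scale variants). Outputs are TSV:
per-replicate stage records, stage-count logs, pedigree, and a
replicate-aggregated summary with means and SDs.

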