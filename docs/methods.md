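# Methods

`breedsim` is a forward-in-time, individual-plant, locus-level simulator of
crop breeding programs.  This note documents the genetic model, the
calibration conventions, the scheduling engine, and the design choices made
where more than one reasonable construction exists.

## Genetic model

**Genome.** A genome is `n_chrom` chromosomes measured in Morgans.
Selectable loci (bi-allelic, allele codes 0 = wild type, 1 = mutant) are
evenly spaced; each is either a QTL or a neutral marker.  QTLs are
designated either as every N-th locus (1-based within its chromosome), by an
explicit index list, or as a random subset of a given size — the last mode
mirrors programs where QTLs are an unknown subset of a real marker panel.  A
separate set of equidistant neutral *IBD loci* per chromosome carries
integer founder labels and plays no role in selection; it exists purely to
measure realized (identity-by-descent) inbreeding.

**Meiosis.** Crossover counts per chromosome are Poisson with mean equal to
the map length in Morgans; breakpoints are uniform; the starting strand is
uniform; there is no interference, no sex difference, and no variable
recombination map.  A breakpoint falling exactly on a locus (a measure-zero
event in continuous coordinates) assigns the locus to the left segment.
Mutation is recurrent bi-allelic: a mutation event toggles the allele, applied
independently per locus per transmitted gamete at the configured rate.
By default mutation operates only during the founder phase; the breeding
phase is mutation-free.

**Founder population.** When no external genotypes are supplied, initial
diversity and LD are built by a Fisher-Wright process: an all-wild-type
population of `n_pat + n_mat` plants mates randomly without selfing
(disjoint paternal/maternal pools, re-randomized each generation) for
`ng_founder` discrete generations, with mutation, drift, and selection —
each generation the 5% (configurable) of offspring with lowest TBV are
culled and replaced by freshly drawn matings.  An optional per-generation
size schedule allows expansion/contraction to shape long/short-range LD.
The final generation's haplotypes are pooled; base plants draw two
haplotypes per chromosome without replacement (replaced between plants), and
self-pollinated (inbred-line) base plants copy haplotype 1 into haplotype 2.
Defaults (50 + 50 founders, 100 generations, 2.5e-3 mutations per locus per
meiosis) put ~400 of 500 loci into segregation at mutation-drift-selection
balance with mean heterozygosity ~0.2 — a plausible stand-in for the
commercial wheat panel scale of diversity.

**Traits.**  TBV is additive over QTLs: `g_i = sum_j x_ij a_j`, dosage
`x_ij in {0,1,2}`.  Single-trait mutant effects are Exponential(1)
magnitudes, negative with probability 0.9 (mutations deleterious on
average); the rate is immaterial because effects are standardized.
Correlated traits share the QTL set, with per-QTL effect vectors drawn i.i.d.
from N(0, Sigma_g) for a user covariance Sigma_g.  Phenotypes are
`y = g + e`, `e ~ N(0, sigma_e2)` i.i.d. across plants, traits and
observations; there are no spatial, common-plot, dominance or epistatic
effects.

**The variance scale.**  `sigma_g2` is the Hardy-Weinberg (non-inbred,
outbred-scale) additive variance.  Effects are standardized so that this
scale is exact; a cohort of fully inbred lines drawn from the same pool then
carries `2 * sigma_g2` between-line variance.  This convention is forced by
the plot-heritability calibration (below), and it is why the shipped plans
(whose base plants are inbred lines) start around genetic variance 2 and the
phenotypic-selection plan still shows variance ~1.4 at the horizon.  Two
standardization routes exist:

* `standardize_effects(effects, cohort, target)` rescales per trait so the
  *given cohort's* realized TBV variance equals the target exactly (the
  testable contract);
* the engine instead standardizes against the founder pool's exact
  haplotype-TBV variance (`2 * var_hap = sigma_g2`).  With a scaled pool of
  ~100 haplotypes, a few-hundred-plant cohort's variance estimate can be off
  by tens of percent (haplotype TBVs are heavy-tailed), and that error would
  propagate into every residual-variance calibration; the pool-exact route
  removes this replicate-level jitter.

**Plot heritability.**  A plot of `Ns` plants is scored as the *sum* of its
members' phenotypes; plot heritability `h2_plot` is the squared correlation
between plot TBV sums and plot phenotype sums.  Under Hardy-Weinberg
proportions with homozygosity `H`, between-line genetic variance `2 H
sigma_g2` is signal while within-line genetic variance `(1-H) sigma_g2`
joins the residual, giving the closed form

    sigma_e2 = 2 Ns H sigma_g2 (1 - h2_plot) / h2_plot - (1 - H) sigma_g2

which reduces to `2 Ns sigma_g2 (1 - h2)/h2` for fully inbred lines (H = 1)
and errors with the attainable bound when the target is infeasible.  `H` can
be supplied as the selfing-generation expectation `1 - (1/2)^t` or measured
from a cohort (`realized_homozygosity`).  The shipped plans calibrate the
preliminary-yield trait (YP, target 0.2) at its single-plot F5 stage and the
advanced-yield trait (YA, target 0.3) at its 9-plot F6/F7 stages, using the
selfing-expectation H for those generations (0.9375 and 0.96875); the
breeder's-visual-preference trait (BVP) uses an individual-plant
heritability of 0.1.  Calibration is exact only for an unselected,
fully inbred, HWE cohort; under selection the realized value drifts, which is
why an explicit measure-and-recalibrate loop is the field's practice — here
the calibration is done once per configuration, not per stage.

**Inbreeding.**  Pedigree F is Wright's coefficient, maintained
incrementally at creation: selfing `F = (1 + F_parent)/2`, doubled haploids
`F = 1`, crosses `F = a(sire, dam)/2` with the additive relationship
computed by a memoized tabular recursion (clones and DH offspring relate to
third parties exactly as their progenitor does).  Realized inbreeding is the
fraction of IBD loci whose two labels match; base plants get globally unique
labels (one per haplotype, or one per plant when inbred).  The two measures
estimate the same quantity and track each other in random-mating tests.

## Breeding-value prediction and selection

Truncation selection operates at three units: population (top n plants),
within family (top n per family), and entire family (top n families by
summed criterion, ties broken by ascending id throughout).  Threshold
selection keeps every candidate at or above a phenotype cutoff.

BLUP/GBLUP solve Henderson's mixed-model equations for `y = Xb + Zu + e`,
`u ~ N(0, K (x) Sigma_g)`, with `K = A` (pedigree numerator matrix) or
`K = G` (VanRaden method 1 over marker loci — QTLs excluded, since their
identity is unknown to the in-world breeder — centered at base-population
allele frequencies frozen at pool construction; monomorphic loci dropped; a
singular G is blended `0.99 G + 0.01 I` and logged).  Fixed effects are an
overall mean per trait, fitted only for traits with records.  Variance
components are the simulation's true values — the breeder is given oracle
variances; REML is out of scope.  Repeated plots of a line enter as repeated
records; the engine's genomic stages use line-mean records with residual
variance `sigma_e2 / n_members`.

In the genomic-selection plans, each GS stage appends its line means to an
append-only reference population (first genotyped at the line-founding F4
stage) and solves a *multi-trait* GBLUP over all recorded traits, ranking
candidate lines on the GEBV of the breeding-goal trait (YA).  This matters:
at the F5 stage only the early yield trait YP has own-performance records,
and with a genetic correlation of 0.3 a single-trait YP prediction carries
almost no YA information — the multi-trait model is what lets genomic
selection act on the goal trait three generations earlier than phenotypic
selection can.

Optimum-contribution selection maximizes
`U(c) = c'a - (omega / L^2)(c + Pv)' A (c + Pv)` over the simplex
`c >= 0, 1'c = 1` (hermaphroditic single pool; optional per-candidate cap),
with `L = 1` by default so `omega` is the single user-facing knob.  The
`omega = 0` case is solved exactly (greedy fill from the top EBV under the
cap); the concave case uses SLSQP from a uniform start with tolerance 1e-12.
Contributions convert to integer mating counts by largest-remainder
apportionment.

## The engine

A breeding plan is a cycle of `n` generations, each with a calendar offset
(time steps since the cycle started), a phenotyping block, an optional
selection rule, optional germplasm storage, and a propagation rule (selfing,
crossing, cloning, or DH; seed counts resolved per plant or per family).  A
new cycle starts at every time step, so at steady state one cycle occupies
every distinct offset; speed breeding is expressed purely by the calendar
(the compressed generations execute back-to-back within one step, oldest
cycle first, generations in order).  The first `founder_cycles` cycles draw
parents from the founder pool; later cycles draw them from stored germplasm
— by default uniformly without replacement from the most recent storage
steps (stored entries are already selected material), with a
truncation-on-stored-criterion policy available.  Crosses among parents are
unordered pairs without selfing or reciprocals under a per-parent usage cap,
drawn by rejection with a seeded usage-balanced greedy fallback for tight
caps.  An optional burn-in switch runs baseline (phenotype) criteria before
a given step; genotyping and reference accumulation also start at the
switch.  Line genotypes are stashed at the line-founding stage so cohorts
already past that stage when the switch arrives can still be genotyped on
demand.

Each stage emits one record — cohort size, family count, per-trait mean TBV
and phenotype, total/within/between-family variance (n-1 denominators;
between-family from size-weighted family means, so the decomposition is
exact), selection accuracy (criterion-TBV correlation, at family-sum level
for family units), and mean pedigree and IBD inbreeding.  The rate of
genetic gain over a window is the OLS slope of final-generation mean TBV on
time step — chosen over an endpoint difference for noise robustness.
Replicates run on seeds `base_seed + i`, each with its own founder
population by default; a run is bit-reproducible given its seed.

## The shipped wheat plans

Plan A (phenotypic selection): 20 inbred parents, 50 of 190 possible crosses
(per-parent cap 5 — the minimum feasible cap, since 50 crosses of 20
parents require an average usage of 5), single F1 per cross, selfing through
F8 with the published funnel: F2 within-family BVP 5/10; F3 entire-family YP
45/50 (three plots); F4 within-family BVP 5 per family founding 225
single-seed-descent lines; F5 line YP 75/225 (one plot); F6 and F7 line YA
30/75 and 5/30 (nine plots); 900 seeds per selected line; germplasm stored
at F5/F6/F7; from cycle 8 parents come from stored germplasm.  Traits: BVP,
YP, YA with unit variance, r(YP, YA) in {0.1, 0.3, 0.5, 0.7} (0.3 shipped),
BVP uncorrelated.  Plan B: identical through a 10-year burn-in, then the 225
F4 per cycle are genotyped, the reference grows yearly, and F5-F7 select on
multi-trait GEBV of YA.  Plan C: plan B with F1-F4 compressed into one time
step (5-step cycles, first 5 cycles from founders).

**Reduced scale.**  The `_small` configs divide cohort sizes by 5 (10
crosses of 10 parents, cap 4; 45 lines; 15/6/1 line funnel; 180 seeds per
line; reference +45/year) on 1 chromosome, 500 loci, every 10th a QTL.  The
map length is 3 Morgans: a single-chromosome surrogate must compress the
~33-Morgan, 21-chromosome wheat map, and the choice trades two failure modes
observed in sensitivity runs — at 1 Morgan hitchhiking on a fully linked
genome exhausts all genetic variance by mid-horizon (the effective
population is ~5x smaller than at full scale), while at 10 Morgans the
450-marker panel is spread to ~22 cM and genomic prediction collapses.  At
3 Morgans the marker spacing (~0.6 cM) matches the full-scale panel's
density and variance persists through the 25-year horizon.  Plan
comparisons pair replicates across plans (shared seeds, hence shared
founder pools and identical pre-burn-in trajectories) and use 60 replicates,
the full-scale study's replicate count: the reduced final generation
contains a single released line, so per-replicate gain slopes are noisy
(between-replicate SD comparable to the mean for the phenotypic plan), and
even 60 replicates leave the gain-rate ratios with standard errors around
0.2.  At this scale the speed-breeding plan more than doubles the
phenotypic rate of gain, while the genomic-selection plan reaches about
1.8x - the reference population and marker panel, both cut 5-20x, bound
genomic-prediction accuracy harder than phenotyping is bound.

**What the scaled experiment does and does not show.**  It reproduces the
*mechanisms* — genomic selection roughly doubling the phenotypic rate of
gain by acting on the goal trait at F5, speed breeding adding more by
recycling parents faster, phenotypic selection retaining the most genetic
variance — and the orderings among the three plans.  The absolute full-scale
gain rates (0.08-0.46 standardized units/year) are not reproducible here:
they depend on the proprietary founder genomes, the 8543-marker panel and
the 225-line/year reference, all 5-20x larger than the scaled study.  The
generator also omits features of real data (genotyping error, shared plot
environments, genotype-by-year noise beyond the correlated-trait device), so
passing tests demonstrate internal consistency of the model, not field
realism.

## Numerical choices and limitations

* Dense linear algebra throughout; MME systems up to a few thousand
  equations solve in milliseconds-to-seconds.  Cholesky failure of K
  triggers an error (BLUP) or the G-blend (GBLUP).
* Gamete sampling is vectorized over plants and chunked (8192 rows) per
  chromosome; RNG draw order is fixed (Poisson counts, breakpoints, starting
  strands, mutations) so results are independent of chunking.
* Ties anywhere in selection break by ascending plant id; cross enumeration
  retries rejection sampling 1000 times before the greedy fill.
* The pedigree kinship cache grows with cross queries; plans dominated by
  selfing keep it small.
* Not modeled: dominance, epistasis, tetraploidy, genotyping error,
  crossover interference, variable recombination maps, REML variance
  estimation, single-step GBLUP, Bayesian marker models, minimum-coancestry
  mating, competing programs.
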