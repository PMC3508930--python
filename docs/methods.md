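# Methods

This note records the statistical models implemented in `ystrat`, the
defaults they ship with, and the choices made where the design was open.

## Data and the packaged fixture

All frequency-based analyses operate on a populations x haplogroups integer
count matrix; all STR-based analyses operate on per-individual records of 17
integer repeat counts (the Yfiler panel minus the multi-copy DYS385a/b
pair). The packaged fixture reconstructs the 31-population Tamil Nadu survey
(1680 Y chromosomes, 21 haplogroups) from its printed percentage table:
counts are the nearest integers (ties to even) of `freq x N / 100`, and the
transcription is accepted only because every row, group-total and
grand-total checksum passes (see `src/ystrat/data/tn31_provenance.md`).
The published per-population diversities are carried along for
cross-checking but every statistic is recomputed from counts.

## Diversity and enrichment

Gene diversity is Nei's unbiased estimator `D = n/(n-1) (1 - sum p_i^2)`
with Nei's sampling variance. Lineage-class proportions (e.g. putatively
autochthonous vs West-Eurasian lineages) are pooled binomial proportions
with `SE = sqrt(p(1-p)/n)`; the class sets are configuration, not code
constants, because published class proportions cannot be reconciled with a
single bipartition of the 21 haplogroups. Enrichment of a haplogroup in a
population group is a Fisher exact test on the chromosome-level 2x2 table;
a second-level test asks whether the number of *populations* over-represented
in the haplogroup concentrates in the group. Both two-sided and one-sided
p-values are reported because the sidedness of the published tests is not
stated. The default over-representation rule — population frequency strictly
above the pooled frequency — is the simplest rule consistent with the text;
a per-population Fisher criterion is selectable.

## Hierarchical AMOVA, R_ST and the grouping bootstrap

AMOVA partitions squared inter-individual distances at three levels
(groups / populations within groups / individuals within populations) with
the standard unequal-sample-size coefficients n', n'', n'''. Distances are
0/1 haplogroup identity for count matrices and summed squared repeat
differences for STR tables; the latter makes the two-population fixation
index Slatkin's R_ST. Both sums of squares reduce to sufficient statistics
(class counts, per-locus sums and sums of squares), so no pairwise matrix
is formed outside the test oracles. Negative variance components are
reported as estimated; `clamp=True` truncates them at zero. Permutation
nulls follow the three standard schemes (populations among groups;
individuals among populations within groups; individuals among populations)
with `p = (#null >= obs + 1)/(n_perm + 1)`, switching to exhaustive
enumeration when fewer distinct permutations than requested replicates
exist.

The grouping comparison bootstrap resamples individuals with replacement
within each population (a multinomial draw over its haplotype counts, sizes
preserved) and recomputes F_CT, reporting median and central 95% interval
over 500 replicates by default. Within-population resampling preserves the
sampling design and is the conservative reading of the published procedure;
pooled resampling across populations is available by flag. Two groupings
are declared ordered only when their intervals are disjoint; touching
bounds count as overlap.

## Ordination

PCA is covariance-mode (column-centred, no variance scaling). Two units are
supported: rows of a population frequency matrix, and — the genotype-PCA
convention — per-individual 0/1 haplogroup indicators expanded from a count
matrix, with population coordinates obtained by projecting frequency
vectors onto the individual-level eigenbasis. The survey's published
two-component variance figure is reproduced by the individual-indicator
unit (36.2%), not by the 31-row population matrix (61.3%); the package
exposes both and the acceptance script reports the individual-level value.
A scree rule (component count before the largest successive eigenvalue
drop) is advisory output only.

Non-metric MDS minimises Kruskal stress-1 by SMACOF majorisation with
isotonic (monotone) regression, best of 20 random starts by default,
convergence at stress change < 1e-9, stress reported in percent. Negative
R_ST estimates are shifted to a valid dissimilarity before embedding.

## Reduced-median networks

STR haplotypes within one haplogroup are expanded locus-wise into ordered
binary "ladder" characters so each unit repeat step is one character; locus
weights default to inverse average repeat variance normalised to mean 10
and rounded to integers >= 1. The network construction iterates: build the
minimum spanning network (union of all minimum spanning trees) under
weighted distance; propose coordinate-wise medians of linked triplets;
retain a median when the star through it is shorter than the reduction
coefficient (default 1.0) times the triangle perimeter; prune inferred
nodes of degree < 3. The result always contains every observed haplotype
and a minimum spanning tree of them. The exact parameterisation of the
original desktop program is not recoverable from the publication, so tests
target structural invariants and hand-checkable cases rather than published
figures. The population-segregation score (fraction of adjacent observed
nodes sharing a majority population label, with a label-permutation null)
is this package's own summary of what the publication judged visually, and
is flagged as such in reports.

## STR-variance dating

Lineage age is `age = Var / w x g`, where `Var` is the across-locus mean of
per-locus repeat variances (n-1 denominator), `w = 6.9e-4` per locus per
generation is the effective mutation rate, and `g = 25` years. These
constants are config defaults justified by exact reconstruction of the
published age table (75 of its 76 variance/age pairs round-trip to < 0.3%;
the one exception is a demonstrable last-digit misprint, pinned in the test
suite). Cells with fewer than 5 complete haplotypes are excluded, mirroring
the published rule. The across-locus standard error of the mean variance
propagates linearly to an age SD; mutation-rate uncertainty is not
propagated.

## Coalescent split-time inference

The sampler targets the joint posterior of genealogy, population split
times, deme sizes and mutation rate for up to four demes under the
structured coalescent with no gene flow. Model:

* demes are constant-size haploid populations (N_e per deme and per
  ancestral branch); growth is deliberately not sampled — a simplification
  of the exponential-growth-from-constant-size family chosen for desk-scale
  mixing, and the main known limitation;
* the 17 loci share one genealogy (no recombination on the male-specific
  Y) and evolve by the single-step SMM; the net repeat displacement over
  `mu t` locus-generations is Skellam, `P(k) = e^{-mu t} I_k(mu t)`;
* split times have uniform priors, Uniform(0, 100 Kya) at the root and
  Uniform(0, parent) below; sizes are Lognormal(median 1000, sigma 1.5);
  `mu ~ Gamma(shape 10, mean 6.9e-4)` — an informative effective-rate
  prior, without which the mu x tau ridge is unidentified at these sample
  sizes;
* generation length 25 years converts generations to years.

The likelihood of the allele matrix given a genealogy is Felsenstein
pruning over a banded allele space (observed range plus 15 states of
padding each side; the band is shared across loci through per-locus
offsets). Moves: node-time slides, nearest-neighbour interchanges,
split-time random walks, size and rate random walks, a global time scaling,
a likelihood-invariant joint rescaling (mu x c, times / c) that traverses
the rate-time ridge cheaply, and for three or more demes an
independence-style proposal of the ranked population topology with prior
split times, accepted only when the current genealogy remains valid.
Genealogy validity (no cross-deme coalescence below the relevant split) is
enforced through descendant-deme bitmasks. Chains initialise from
moment-based starting values: pairwise split guesses from between-deme
minus within-deme allele-size variance, capped by the closest cross-deme
haplotype distance, and a genealogy simulated under that demography.

Verification: branch probabilities and the pruning recursion match explicit
mutation-path enumeration on fixed tiny genealogies to 1e-8 and better; the
structured-coalescent prior matches a closed-form hand case exactly; the
incremental caches are cross-checked against full recomputation inside the
sampler when `check_every` is set. At the reduced scale used throughout
(n = 20 per deme, 60k samples, 20k burn-in), the 95% credible interval of
the root split covers a simulated 10 Kya truth in 19 of 20 seeded
replicates. Effective sample sizes at these chain lengths are modest
(~10-20); results carry a convergence flag and posteriors should be read as
reduced-scale demonstrations, not production estimates.

### Admixture sensitivity scenarios

Three label perturbations probe the no-gene-flow assumption: randomly
splitting one panmictic deme (the split-time posterior collapses below 500
years, matching the published behaviour); symmetrically swapping 10% of
chromosomes between two demes split 10 Kya (the estimate drops by well over
half — swapped close relatives force recent cross-deme coalescences); and
replacing up to 40% of two host demes with migrants from a divergent third
deme. For the third scenario the published claim is near-insensitivity; the
exact posterior of the model does not reproduce it. Random migrants drawn
from a single source deme regularly include close patriline relatives with
identical 17-locus haplotypes, and placing such a pair on both sides of the
split forces the same collapse as scenario two (verified from both low and
high chain starts and across host sizes 300-2000 and fractions 0.2-0.4).
The corresponding acceptance test is therefore expected to fail and is left
failing deliberately; the mechanism is documented rather than patched
around.

## Synthetic data: what it does and does not emulate

`simulate_dataset` draws one genealogy per dataset from msprime under a
dated population-split demography (ploidy 1) and evolves repeat counts by
Poisson-count single-step walks down the tree from a founder allele of 25;
haplogroup labels are inherited from the genealogy root's child lineages as
perfectly linked markers without recurrent mutation. Defaults — 17 loci,
`mu = 6.9e-4`, g = 25 y — match the dating convention above. The generator
reproduces the coalescent structure the analyses assume but none of the
measurement realities of real Y-STR data: no missing calls, no multi-step
or locus-specific mutation, no allele-range constraints or stutter, and no
haplogroup homoplasy. Passing tests therefore validate the estimators under
their own model assumptions, not robustness to those artefacts.

## Numerical conventions

Counts reconstruct with ties-to-even rounding and mandatory checksums.
Missing repeat counts use a sentinel and are excluded (with counts logged)
by STR analyses rather than imputed. Permutation and bootstrap p-values
use the add-one rule. All stochastic code takes explicit integer seeds;
simulation, bootstrap and MCMC runs are bit-reproducible given a seed.
Problem sizes in the test-suite and in `scripts/acceptance.py` (5 seeds at
100k MCMC samples for the deme-split scenario, 5 seeds at 40k samples per
arm for the mixing scenario, 20 replicates at 60k samples for coverage)
are the package's desk-scale choices; larger runs only tighten the same
estimates.
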