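# Methods

This note records the models implemented in `crosspred`, the assumptions
behind them, and the numerical choices made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotype coding and QC

SNP calls count copies of the alphabetically-first nucleotide allele, so
every call is 0, 1 or 2 with heterozygotes at 1.  Since the intended
material is near-homozygous inbred lines, heterozygous calls are retained
verbatim (no het-to-missing recoding).  Markers are dropped when minor-
allele frequency (computed over observed calls only — the only reading
self-consistent with a joint MAF/missingness filter) falls below 0.06 or
when more than 20% of calls are missing.  A marker failing both filters is
booked under missingness, which is checked first; this keeps the QC report
counts disjoint and reproducible.  Filtering precedes imputation: computing
MAF on imputed calls would let the imputer influence which markers survive.

Residual missing calls are filled by a deliberately naive single-marker
imputer (per-marker mode, or rounded mean).  Haplotype-phasing imputation
is out of scope; on chip data that passed the missingness filter the two
differ for at most 20% of calls at a minority of markers, and every
downstream stage is agnostic to how gaps were filled.

## Trial mixed model

Multi-environment yield trials are analysed with

    y = mu + E + M + E(r) + G + E(G) + e

where environment `E` (year × location), the maturity covariate `M` and
replicate-within-environment `E(r)` are fixed, and genotype `G` and
genotype-by-environment `E(G)` are random.  Maturity enters as a single
linear covariate in days — the minimal reading of "adjusting for maturity";
no polynomial or spline is attempted.  Variance components are estimated by
EM-REML on Henderson's mixed-model equations: convergence when the relative
change of every component falls below 1e-6 (at most 500 iterations),
negative iterates floored at zero (boundary REML).  On balanced data with
interior estimates this fixed point coincides with the ANOVA
expected-mean-squares estimator, which the tests exploit as an independent
oracle.  Entry BLUPs are the `G` solutions, reported as deviations; the
validation stage consumes deviations consistently, so no re-centering to
the trait scale is performed.  With a single environment `sigma2_GxE` is
inestimable and reported as 0 with a confounding flag.

Entry-mean heritability is `H2 = s2G / (s2G + s2GxE/e + s2R/(e r))` for a
trial with `e` environments and `r` replicates.

## Progeny simulation

Meiosis follows the chi-squared crossover-interference model at
interference parameter m = 0 — i.e. no interference: per chromosome the
crossover count is Poisson with mean equal to the map length in Morgans and
positions are uniform on the mapped interval.  This is the only reading
consistent with invoking the chi-squared model "assuming no interference",
and it reproduces Haldane's map function `r = (1 - e^(-2d))/2`, which the
tests verify directly.  No obligate chiasma is enforced (a meiosis may pass
a chromosome through intact), matching the Poisson assumption.  Markers at
identical positions always co-segregate.

RIL progeny are produced by single seed descent: each progeny traces to an
independent F1 meiosis (one gamete per parent), then each generation selfs
a single plant by drawing two independent gametes, to F5 by default.
F5-derived lines retain residual heterozygosity — about 1/16 per originally
segregating locus, since heterozygosity halves each selfing from 1/2 at F2
— and calls of 1 are emitted as such rather than forced homozygous.
Phasing of a (rare) heterozygous parental call uses one coin flip per
chromosome; true phase is unknowable from single-site calls and the target
material is near-homozygous, so no LD-based phasing is attempted.

## Genomic prediction

All models work on centered scores: call − 1 mapped to {−1, 0, +1}, columns
centered by *training-set* means, with the identical transform applied to
any new genotypes (the standard VanRaden convention; the training means are
stored in the fit object).

* **RR-BLUP** — ridge mixed model `y = 1mu + Zu + e` with iid marker
  effects; the variance ratio is found by REML on the spectral
  decomposition of ZZ', making the cost O(n³) in lines, independent of
  marker count.
* **BayesRR / BayesB** — single-site Gibbs samplers (numba-compiled,
  deterministic given a seed), 1,500 iterations with 500 burn-in by
  default.  BayesRR shares one effect variance across markers with a
  scaled-inverse-chi-squared hyperprior; BayesB gives each marker its own
  variance and a prior point mass `pi = 0.95` at zero effect (sampled via
  the marginal Bayes factor).  The hyperprior degrees of freedom are 4.2
  and the scales assign half the phenotypic variance to markers and half
  to noise; none of these constants are estimates — they are declared
  defaults, configurable, chosen in line with common whole-genome
  regression practice.  A `fix_variances` option freezes both variances,
  reducing the sampler to Monte-Carlo ridge regression — the closed-form
  oracle used in the tests.
* **EGBLUP** — `y = 1mu + g1 + g2 + e`, `g1 ~ (0, G·s2a)`,
  `g2 ~ (0, H·s2aa)`, with `G` the additive kernel (ZZ'/c, `c` chosen so
  the mean diagonal is 1) and `H` the Hadamard square of `G`, rescaled the
  same way so the two variance components are comparable.  `H` is PSD by
  the Schur product theorem.  The two variance ratios maximize the
  profiled restricted likelihood directly (Nelder-Mead on log ratios with
  the residual variance and intercept profiled out analytically).  A
  component-wise EM-REML was the first design here, but at
  training-population sizes in the thousands its per-iteration full-matrix
  inverse and slow linear convergence made it an order of magnitude more
  expensive than direct maximization for identical optima, so the direct
  method is the implementation; `precise=True` tightens tolerances and
  adds restarts for the equivalence tests.  Kernel inversion uses a ridge
  jitter of 1e-8·n.

Prediction for unphenotyped progeny: marker-effect models score
`mu + z·u` directly; EGBLUP extends both kernels to the new lines with
training centering and projects each component,
`g_new = K_new,train (K_train,train + eps·I)^-1 g_train`, equivalent to
solving one joint mixed model with the new lines unphenotyped (the tests
verify this against a Henderson-MME oracle).

Dominance kernels are deliberately absent: dominance variance does not
exist in RIL populations.

## Usefulness criteria and ranking

The cross value is `UC = mu + i·sigma_g` operationalized as the mean of the
top-`i` fraction of predicted progeny GEBVs; `i = 0` is the progeny mean.
The head count is `k = max(1, round(i·n))` with round-half-away-from-zero —
at the default 500 progeny, `i` of 0.1/0.2 select exactly 50/100, so the
rounding rule only matters for other progeny counts.  The progeny GEBV
standard deviation (denominator n − 1) is reported alongside, preserving
the `mu + i·sigma` interpretation.  One progeny set per (cross, seed) is
shared across criteria and across models scored in the same run, so method
comparisons see identical progeny.  Selfs are excluded from enumeration by
default.  Ranking ties break on the lexicographic cross id.

## Validation design

Each validation replicate samples crosses without replacement, builds the
requested training compositions, fits every model on the retained lines,
simulates each sampled cross's progeny once, and records the Spearman rank
correlation (average ranks for ties) between predicted and observed cross
values — the observed value being the mean entry BLUP of a cross's
phenotyped progeny.  "Direct progeny" for WFS means lines whose recorded
cross-of-origin is one of the predicted crosses; grandprogeny are not
removed.  RTS removals are uniform without replacement among non-progeny,
non-parent lines and are re-drawn per replicate under the replicate seed;
parents are never removed under any composition.  All randomness descends
from one master seed through `numpy.random.SeedSequence` spawning, so a
full validation is bit-reproducible.

## Synthetic scenarios

The generator emulates an elite inbred program.  Founders are fully
homozygous with per-marker allele frequencies drawn U(0.1, 0.9) — a
spectrum that keeps most markers polymorphic after QC, echoing chips
designed for common variants without modelling ascertainment.  Markers are
placed uniformly on each chromosome.  The default stated world is
soybean-sized: 20 chromosomes of 125 cM, ~3,800 markers, 35 founders, a
702-line training population, 42 validation crosses with 16 phenotyped
progeny each, and h² = 0.5 — typical of multi-environment yield trials.
The trait has 100 additive QTL with standard-normal effects plus 30
additive×additive pairs sampled among them (pair effect × score_i ×
score_j), a generic polygenic yield architecture chosen once as a
modelling decision, not an estimate.  QTL are markers themselves by
default; a `mask_qtl` flag removes them from the panel to emulate
marker–QTL LD.  Residual noise is rescaled so the realized
var(g)/var(y) hits the target h² exactly.

Training lines descend from the founders through two generations of random
crossing, each followed by single seed descent (vectorized across crosses).
Validation crosses are sampled among a founder-sized subset of training
lines; their realized progeny are phenotyped and join the line set, with a
pedigree recording cross of origin so WFS/RTS compositions can be built.

What a green test on this generator establishes: that the pipeline
recovers rank information about cross values under a known additive +
epistatic architecture with realistic map, population and heritability
scales.  What it does not establish: performance on real germplasm —
ascertainment bias, population structure, genotype-by-environment patterns
and selection history are not modelled, so empirical accuracies on real
programs cannot be inferred from these simulations.

## Known limitations

* Imputation is single-marker; no haplotype phasing.
* Crossover interference beyond m = 0, sex-specific maps, and selection
  during inbreeding are not modelled.
* No multi-trait index selection, mating-plan constraints, or optimal
  contribution theory.
* The Bayesian samplers report posterior means only; no convergence
  diagnostics beyond the chain-length stability checks in the tests.
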