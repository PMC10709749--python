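# Methods

## Study design being modelled

A longitudinal pelvic-radiotherapy cohort: 16 patients, five stool samples
each — before RT (prRT, day 0), two and five weeks after RT start (RT-2w,
day 14; RT-5w, day 35), and one and three months after RT completion
(poRT-1m, poRT-3m). One sample is lost, giving 79 samples. Seven of sixteen
patients experience acute GI toxicity (RTOG grade ≥ 1); this binary flag is
the analysis factor. The post-RT day values (defaults 86 and 146) are a
convention — they assume an ~8-week course plus 30/90 days — and are
configurable, since calendar anchors for "1 month after completion" depend
on the course length.

## Statistical pipeline

**Normalization.** Counts are scaled linearly so every sample's total
equals the cohort's maximum read count ("normalized to the maximal read
count" read literally); this preserves within-sample proportions exactly.
Rarefaction (seeded subsampling without replacement) is provided as an
alternative for users who prefer equal-depth count data; linear scaling is
the default because it is deterministic and loses no reads.

**Alpha diversity.** Shannon entropy H = −Σ p ln p (natural log; the base
only rescales and is configurable). Group comparison per timepoint uses the
package's Wilcoxon rank-sum: exact enumeration when the pooled sample is
tie-free with n ≤ 12, otherwise a tie-corrected normal approximation with
continuity correction.

**Beta diversity.** Generalized UniFrac with exponent α on the branch-wise
total proportion; α = 0.5 by default (the moderate weighting recommended by
the method's authors), α = 1 reduces to weighted-normalized UniFrac (the
test suite verifies this against scikit-bio to 1e-10). Branches with no
descendant mass in either sample are skipped. Ordination is classical
scaling (PCoA) of the distance matrix: eigendecomposition of the
double-centered −D²/2, axes with negative eigenvalues reported and dropped,
proportion explained taken over positive eigenvalues. "PCA based on
generalized UniFrac" can only coherently mean PCoA, and that is what is
implemented. PERMANOVA uses the standard pseudo-F from within-group squared
distances, free label permutation, and the add-one permutation p-value
p = (1 + #{F* ≥ F}) / (B + 1) with B = 999 by default; pairwise tests are
BH-corrected jointly. A within-stratum (e.g. within-patient) restricted
permutation mode exists but is off by default, since the published analysis
describes no restriction.

**Association testing.** Per taxonomic level: taxa are kept when their
maximum relative abundance across samples reaches 0.01 (a mean-based filter
is available), tested by Wilcoxon rank-sum between toxicity groups, and
BH-corrected within the level. Effect size is the generalized fold change:
the mean difference of matched quantiles (default grid 0.05, 0.15, …, 0.95)
of log₁₀(abundance + 1e-5). Positive gFC means toxicity-enriched. Per level,
the significant (q < 0.05 by default) taxon with maximal gFC joins the
toxicity-representative set T, the minimal one joins N; a side with no
significant taxon contributes nothing and warns.

**MCPI.** MCPI_j = ln(Π_T (A_ij + c) / (Π_N (A_ij + c) + ε) + 1) on relative
abundances. ε (default 1e-8) guards the denominator; a pseudocount
c (default 1e-6) keeps zero abundances from annihilating the products —
with c = ε = 0 the literal formula is recovered, and the index equals ln 2
exactly when the two products balance. Published usage is ambiguous between
a family-level-only index and a mixed three-level T/N set; both modes are
implemented (`mcpi_mode="family"` / `"mixed"`), with mixed as the pipeline
default, each taxon's abundance read from its own level's table. Groups are
compared at each timepoint by one-way ANOVA (equivalently a pooled-variance
t-test, F = t²).

**Longitudinal models.** Per taxon: abundance ~ 1 + days + days² + group +
days:group + days²:group + antihormone + age [+ the other clinical factor],
with a Gaussian patient random intercept, fitted by REML (statsmodels
MixedLM supplies the optimizer; design construction, rank/collinearity
checks, margins and inference are the package's own). The analysis factor
(toxicity or RT field) always carries the quadratic-day interaction — the
source description of which factor interacts is self-contradictory, so the
factor is a parameter. Predictive margins average the fixed-effect
predictor over the observed covariate distribution; for a linear predictor
this coincides exactly with evaluation at covariate means, so the
`at-means` flag is cosmetic. Contrasts use delta-method standard errors
from the fixed-effect covariance and a chi-squared test with df 1. Raw
relative abundance is the default response (margins on the abundance
scale); log₁₀(x + 1e-6) is available. Non-convergence is surfaced as a flag
plus warning, never silently.

## Synthetic cohort generator

Counts are Dirichlet-multinomial: per sample, proportions ~
Dirichlet(exp(log α₀ + patient intercept + planted effects)), counts ~
Multinomial(depth, proportions), depth ~ negative binomial (mean 30 000,
dispersion 20, iSeq-scale 16S depths). Base concentrations α₀ are log-normal
across taxa (sd 1.5, a realistically uneven community) scaled to a total
concentration of 500. Patient intercepts (sd 0.3 on the log-concentration
scale) induce within-subject correlation across the five visits. The tree
is a random bifurcating topology with Exponential(mean 0.1) branch lengths —
any rooted tree with positive lengths exercises UniFrac. The lineage map
nests the planted species in dedicated genera/families (two nested genera
per side within one family, mirroring how a family like Fusobacteriaceae is
carried by one genus), with background species grouped 3 per genus, 9 per
family.

**Planted signal.** Three toxicity- and three no-toxicity-associated
species, pinned at base proportion 0.05, receive per-timepoint log-fold
boosts to the affected group's concentrations: (0, 1.7, 2.0, 1.7, 1.2)
across the five timepoints — zero at baseline, peaking at RT-5w. The peak
of 2 natural logs (~7-fold) was chosen by a design-stage power analysis:
with only 7 vs 9 patients, representative selection by extreme gFC is only
reliable when the planted taxa dominate the gFC ranking, as the published
representatives (order-of-magnitude enriched taxa) did. The diversity
deficit divides the toxicity group's total Dirichlet concentration by
(1 + deficit), default deficit 2, at RT-2w/RT-5w: expected proportions are
unchanged (so no artifactual per-taxon association signal is planted), while
within-sample compositional noise grows, depressing expected Shannon
diversity mid-RT.

**What the generator does not emulate.** Read-level errors, chimeras and
contaminants; taxon-taxon ecological interactions beyond compositional
coupling; time-autocorrelated within-patient drift (the patient effect is a
static intercept); overdispersion as heavy as some real gut cohorts (the
total concentration is deliberately on the low-dispersion side so that a
16-patient design has the power the original study evidently had). Passing
recovery tests therefore demonstrates correctness of the pipeline's
inference on data with the assumed structure, not field performance on
arbitrary real cohorts.

**Repeated measures caveat.** Pooled per-taxon rank tests treat the 79
samples as independent. With patient intercepts present, the pooled
Wilcoxon's null is mildly anti-conservative — a property of the original
design, not of this implementation. Calibration properties (null p-value
uniformity, BH behaviour under the global null) are therefore verified at
patient-intercept sd 0, which isolates the exchangeability claim actually
being tested; the LME stage is the pipeline's repeated-measures-aware
analysis.

## Numerical conventions

- Permutation p-values use the add-one estimator (resolution 1/(B+1), never 0).
- Wilcoxon falls back to the normal approximation whenever ties are present;
  exact enumeration is limited to pooled n ≤ 12.
- ANOVA with zero within-group variance: p = 1 when the means agree
  (all-identical data), p = 0 otherwise.
- PCoA eigenvalue positivity tolerance: |λ| > 1e-12 × max(|λ₁|, 1).
- BH is computed by the step-up cumulative minimum; results are invariant to
  input order.
- All randomness (simulation, permutations, rarefaction) flows from explicit
  integer seeds; identical seeds give byte-identical output files.
- Proportion tables must sum to 1 per sample at IO boundaries; in-memory
  sub-community tables (after taxon filtering) may sum to less, never more.

## Problem sizes used in validation

Validation simulations run at the study's own scale (16 patients × 5
timepoints, 120–300 taxa) with 25–200 replicates per property and 99–999
permutations per test, chosen to estimate the relevant rates with adequate
precision at desk scale.

## Known limitations

- Exact Wilcoxon with ties is not implemented (normal approximation is used).
- PERMANOVA is one-factor; no PERMDISP companion test, so location and
  dispersion effects are confounded as in any PERMANOVA.
- The MCPI's value depends on the pseudocount when representative taxa are
  absent from a sample; the config echo in every output records it.
- LME fits on 16 patients occasionally sit at the random-effect variance
  boundary; the convergence flag is propagated rather than resolved.
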