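# Methods

## Amplification-bias model

The calibration stage assumes read-count distortion is multiplicative and
species-specific: a species' template DNA is amplified with relative
efficiency `exp(α_i)` per library, so a true composition `p` is observed in
expectation as `θ_i ∝ p_i·exp(α_i)`. This is the minimal identifiable model
for compositional bias — any per-cycle efficiency difference compounds into
a single log-offset, so PCR cycle number is folded into `α` rather than
modelled separately. Offsets are only identified up to an additive
constant; we pin the alphabetically first mock species at `α ≡ 0`
(configurable). Adding any constant to all offsets leaves both `θ` and the
inverse correction unchanged, so the choice of reference is without loss
(this is covered by an invariance test).

Mock replicate counts enter a multinomial likelihood at `θ` computed from
the control's known proportions. The hierarchical prior
`α_i ~ Normal(0, τ)`, `τ ~ half-Normal(1)` pools across species and keeps
the fit proper when a control contains few species; with 10 mock species
at 50,000 reads the likelihood dominates and the prior's influence is
negligible. A Dirichlet-multinomial likelihood is not fitted: replicate
scatter in the simulated designs is multinomial by construction, and the
correction uses only posterior means of `α`, which are robust to modest
extra-multinomial noise.

### Sampling and diagnostics

The posterior over `(α_free, log τ)` is drawn with an affine-invariant
ensemble sampler (emcee), 32 walkers, vectorised likelihood. The default
settings — 3 chains × 10,000 iterations with a 5,000-iteration warm-up,
thinned by 5 — mirror the calibration protocol this pipeline implements;
the recorded `max_tree_depth` setting is a provenance field with no effect
on an ensemble sampler. Each "chain" is an independently initialised
ensemble (walkers from `Normal(0, 0.5)` overdispersed starts), flattened
walker-major so that split potential-scale-reduction compares disjoint
walker sets across ensembles; `rhat` is therefore conservative, while bulk
ESS computed on pooled walkers can overstate independence — we flag
`rhat > 1.05` or `ESS < 100` as `warn`, and warnings never abort a run.
Tests and the benchmark script use 3 × 2,000 iterations, which on the
two-control/five-replicate design reproduces every design proportion to
well under one percentage point; results are insensitive to chain length
beyond ~1,000 kept draws.

### Correction

Field samples are corrected by the closed-form inverse
`p̂_i ∝ r_i·exp(−α_i)` with `α` at the posterior mean (default) or across
full posterior draws (reporting per-species central 95% intervals; the
point estimate is then the posterior-mean composition). Species absent
from the mocks cannot be calibrated and pass through with `α = 0`;
corrected counts are `p̂ ×` the sample's total reads, preserving depth.
Calibration is invariant to rescaling counts by a positive constant.

## Screening rules

"Exceeds 1%" is read strictly (`> 0.01`): a species at exactly 1.00% in
every sample counts as never present. Support is counted per sample on
proportions (depth-invariant), and species are labelled major (≥ 4
samples), minor (1–3) or excluded (0). Replicates — samples sharing a
declared technical-replicate group, or the same individual and date — are
collapsed to the member with the highest total read count *before* support
counting; the ordering of dedupe and screening is exposed only through
which table the caller classifies, with dedupe-first as the pipeline
default. Ties and all-zero groups (logged) resolve to the lexicographically
smallest sample ID. After restricting a table to major prey, proportions
are renormalised over the retained species — reads from excluded species
are discarded, not redistributed — and samples left with zero retained
reads are dropped with a logged warning.

## Genotype identity

Distance between two samples is allele-sharing distance over co-genotyped
loci, `1 − shared/(2·n)`, with calls coded 0/1/2 (alternate-allele count):
0 for identical calls, 1 for opposite homozygotes, undefined (an error)
with no overlap. Samples below 85% locus completeness are removed first.
Average-linkage hierarchical clustering is cut at height 0.05, tolerating
roughly 2–3 discordant loci on a 68-locus panel — comfortably above the
expected same-individual distance at a 1% per-allele error rate (~0.02)
and far below typical between-individual distances (~0.4 at intermediate
allele frequencies). A sample is "known" when some reference genotype
differs at ≤ 2 co-genotyped loci (fewest mismatches wins; ties to the
smallest reference ID). The five-rule decision tree picks each cluster's
representative; the undefined edge case of a single known sample that does
*not* hold the cluster's highest genotyped fraction is resolved in favour
of the known sample (recorded as rule 2), reading the tree as
"known individuals take precedence". Anonymous clusters receive `UNK_###`
labels numbered in representative-ID order, making assignments independent
of input ordering.

## Diet statistics

PERMANOVA uses the Gower-centred inner-product formulation: with
`G = −½·J·D²·J`, total SS is `tr(G)` and the SS explained by a design with
hat matrix `H` is `tr(H·G)`. Multiple factors are fitted sequentially in
the caller's order (population, month, year by default), each factor's SS
being the increment in explained SS — so R²s depend on order, as in any
sequential decomposition, and sum with the residual R² to 1. p-values
permute sample identities (rows/columns of `G`) with `(exceed + 1)/(B + 1)`
for `B` random permutations, or the plain exceedance fraction under exact
enumeration (available for small n; used by the test oracle). Bray–Curtis
is the default distance; for proportion vectors it reduces to
`1 − Σ min(a_i, b_i)`.

Seasonal profiles pool samples by calendar month across years within each
population or pod, take per-species monthly mean proportions (each sample
weighted equally — robust to depth variation, unlike read-pooling), and
smooth the monthly means with a local quadratic regression: tricube
weights over the `ceil(span·n)` nearest months, default span 0.85, no
circular wrap (curves are drawn on a linear month axis). The local fit
reproduces constants and, at full span, polynomials up to its degree
exactly; smoothed values are clipped to [0, 1]. Groups observed in fewer
than three distinct months raise an error naming the group.

## Synthetic data

The generator produces the study conditions the analysis assumes: ten mock
species across a general and a salmonid-specific control (five replicates
each), 185 field samples at an expected depth of 150,000 reads (the order
of a typical post-QC library), amplification offsets `Normal(0, 0.3)`, and
a 68-locus SNP panel over 20 individuals. Field compositions are Dirichlet
(concentration 5 — wide between-sample variation, as faecal samples show)
around mean compositions built from a Chinook-dominated baseline shifted
on the log scale by three effects: a smooth cosine month effect around
per-species peak months, a population effect, and a pod effect. Known prey
species carry ecology-motivated peaks (Chinook peaking in May and
declining through summer, coho peaking in late summer, chum in autumn,
groundfish in winter) so seasonal-trend recovery has a recoverable signal;
unrecognised species get seeded random phases. Population A is sampled in
all months and population B only May–September, mirroring opportunistic
field coverage. Overdispersion, when enabled, is Dirichlet-multinomial
with the configured precision; the default is pure multinomial. Genotype
samples copy their individual's Hardy–Weinberg genotype (allele
frequencies Uniform(0.1, 0.9)) with independent per-allele error and
per-locus missingness.

What the generator does **not** emulate: sequencing-run batch effects and
index hopping, taxonomy-assignment error, within-individual diet
autocorrelation in time, secondary-prey (prey-of-prey) reads, and
non-closed species sets (every read belongs to a known column). Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical model, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The test suite runs reduced problem sizes chosen for tight feedback:
MCMC at 3 × 2,000 iterations (the full default remains 3 × 10,000),
power checks at 10–20 replicate simulations, the type-I-error study at
1,000 null PERMANOVA runs with 199 permutations each, and genotype
recovery at 20 individuals × 5 samples. The benchmark script uses the
same reduced MCMC setting. Degenerate inputs are handled explicitly:
all-zero mock samples, zero-read field samples and empty filter results
raise typed errors; zero-weight species in a control contribute only
through the `x·log θ` terms where counts are zero; Dirichlet draws are
clipped away from exact zero to keep compositions strictly positive.
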