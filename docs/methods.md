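# Methods

This note documents the statistical procedures implemented in `wildtcr`, the
assumptions behind them, and the design choices made where more than one
reasonable implementation existed.

## Clonotype definitions and ingestion

A T-cell clone is defined at the nucleotide level by the exact combination of
V gene label, CDR3 nucleotide sequence and J gene label; distinct nucleotide
clones that translate to the same amino-acid CDR3 with the same V and J
labels form one amino-acid clonotype. Amino-acid clonotype identity is the
triple `(v_label, cdr3_aa, j_label)` rather than a literal translated
V+J+CDR3 concatenation: given fixed germline references the two are
equivalent, and the triple avoids bundling a germline sequence database into
the package.

Input tables are tab-separated with a required header, in either a minimal
five-column dialect (`v, j, cdr3_nt, cdr3_aa, count`) or the AIRR
Rearrangement subset (`v_call, j_call, junction, junction_aa,
duplicate_count`); AIRR is the interchange default. Counts are molecule
counts and are taken as given (UMI correction is an upstream concern).
Records whose CDR3 nucleotide field is empty, whose length is not a multiple
of three, or whose frame-0 translation contains a stop codon are excluded
under a productive-CDR3 rule; the exclusion report counts each reason
separately so the filtering is auditable. Translation uses the standard
genetic code in frame 0.

## Quality control

For each mouse and T-cell subset (CD4+, CD8+), both chains are dropped if
either chain's repertoire holds fewer than 5000 molecules; exactly 5000 is
kept (the rule is a strict less-than). The decision is logged with both chain
sizes.

## Richness, down-sampling, and diversity

*Repertoire size* is the sum of molecule counts; *richness* is the number of
unique amino-acid clonotypes divided by repertoire size, a depth-normalised
breadth measure computed on the full (not down-sampled) repertoire — since
the ratio already normalises for depth, down-sampling it again would only add
noise. A flag (`richness_on_downsampled`) computes it the other way.

Diversity uses natural logarithms throughout:

* Shannon index: `H = -sum_i p_i ln p_i`,
* Simpson index: `lambda = sum_i p_i^2`, reported as `ln(1/lambda)` so that
  larger values mean higher diversity,

with `p_i` the proportional abundance of the i-th *unique* amino-acid
clonotype (the only reading under which `sum_i p_i = 1`).

Before computing either index, every mouse of a receptor type is
down-sampled without replacement to the smallest repertoire size of that
receptor type. The implemented sampler is a multivariate hypergeometric
draw, which is distributionally identical to the literal procedure of
replicating each clonotype by its count, sampling the list without
replacement and re-tallying; the literal sampler is retained in the code
base as an independent test oracle, and the equivalence contract is
distributional, not byte-level. Down-sampling is repeated independently for
the two indices. Per-mouse sub-seeds are derived by hashing (master seed,
mouse id, receptor type, index name), so adding or removing one mouse never
perturbs another mouse's draw. The clone order fed to the sampler is
canonicalised (sorted keys), so draws depend only on repertoire content.

## Power-law fit and classification

Clone-size distributions (the multiset of amino-acid clonotype counts per
mouse and receptor type) are fitted with the standard discrete power-law
machinery: the exponent is the zeta-function maximum-likelihood estimate at
a lower cutoff `xmin`, `xmin` is chosen to minimise the KS distance between
the empirical tail and the fitted law over observed candidate values (a
fixed `xmin` can be supplied instead), and goodness-of-fit is a
semi-parametric bootstrap: each replicate resamples the observed sub-`xmin`
data with replacement, draws the tail from the fitted law, and is refitted
from scratch including `xmin` re-selection; the p-value is the share of
replicate KS statistics at least as large as the observed one (500
replicates by default). Both the empirical and model CDFs are
right-continuous step functions on the integers, so the KS supremum is
evaluated at observed values only. Fits are classified as `fits`
(p > 0.1), `borderline` (0.05 < p <= 0.1) or `does_not_fit` (p <= 0.05);
boundary values fall into the lower category, which affects only
measure-zero cases. Sampling from the fitted law uses exact CDF-table
inversion up to a cap of 10^6 and a rounded continuous Pareto tail beyond
it.

## Sharing networks, public clonotypes, ordination

Pairwise sharing is computed on repertoires down-sampled to the receptor
type's minimum size and reduced to unique-clonotype sets; `S[i, j]` is the
size of the set intersection for mice i and j, and the diagonal holds each
mouse's down-sampled unique count. The summary "sharing percentage" is the
mean off-diagonal shared count divided by the mean down-sampled unique
count, times 100 — one concrete reading of a pairwise-overlap percentage;
the denominator is parameterised rather than claimed unique.

A clonotype is *public* at threshold t (default 0.75) when present in at
least `ceil(t * n)` of the n mice passing QC for that receptor type.

Dissimilarity between mice is the re-scaled form `d = S_max - S` with
`S_max` the largest off-diagonal sharing count, so the most similar pair has
dissimilarity exactly 0; a relative form `1 - S/S_max` is available behind a
flag. Dendrograms use average linkage (UPGMA) on this dissimilarity, with
scipy's deterministic lowest-index tie-breaking, and can be serialised to
Newick. Ordination is classical (Gower) principal coordinates with optional
observation weights: `-d^2/2` is double-centred with the weighted centring
operator, `diag(sqrt(w)) B diag(sqrt(w))` is eigendecomposed, and
eigenvectors are rescaled by `1/sqrt(w)`; with uniform weights this reduces
exactly to unweighted classical PCoA (verified against scikit-bio), and the
weighted case matches R `vegan::wcmdscale`. Negative eigenvalues are
reported, not suppressed; coordinates are returned for positive axes only.
Uniform weights are the default since no particular weighting is canonical.

## Covariate models and EMMs

Richness is modelled with a gamma-family GLM. The link is log: the response
is strictly positive and multiplicative covariate effects are the natural
default. Shannon and log-Simpson diversity use Gaussian GLMs with identity
link. All three share the design
`receptor_type + site + age + sex + age:sex`. Pairwise sharing uses a
Gaussian GLM on the six-term design `receptor_type + same_sex + age_diff +
age_sum + age_diff:receptor_type + age_sum:receptor_type`. Test statistics
are t ratios on the residual degrees of freedom. Factors with a single
observed level are dropped from the design with a warning; zero-variance
covariates, constant responses and rank-deficient (aliased) designs raise
errors naming the offending terms. Continuous covariates are not
standardised by default (a flag enables z-scaling).

Estimated marginal means average model predictions (on the link scale) over
a reference grid in which factors are crossed with equal weight and
covariates sit at their data means. Pairwise EMM contrasts use the Tukey
studentized-range adjustment — a standard choice where only "corrected for
multiple comparisons" is specified — and agree with R `emmeans` to ~1e-6 on
fixture data (frozen oracle values in the test suite). Per-level covariate
slopes (the EMM trend analogue) are reported with unadjusted t tests.

Pair rows are not independent (each mouse appears in many pairs). The GLM is
nevertheless fitted on them directly, as is conventional for this design; a
permutation test that shuffles mouse ages and recomputes the pair covariates
is provided separately (`sharing_permutation_pvalues`, off by default) for
users who want significance statements robust to that dependence.

## Synthetic cohorts

The generator produces cohorts whose repertoires have the statistical
structure the analysis assumes, so the whole pipeline can be exercised and
validated without any data download. It emulates:

* **Power-law clone sizes.** Counts are drawn from the discrete power law
  `P(k) ~ k^-alpha`, `k >= xmin`, by exact CDF inversion. Default
  `alpha = 2.5`, `xmin = 1`, 5000 unique clonotypes per repertoire —
  desk-scale sizes chosen so a 60-mouse cohort simulates in seconds while
  keeping every distributional feature the estimators see (the deposited
  repertoires are an order of magnitude deeper).
* **A public clonotype pool per chain** (default 3000 keys), sampled per
  mouse without replacement with popularity weights decaying as
  `rank^-1.5`. A small head of pool clonotypes therefore recurs in almost
  every mouse (these become the public clonotypes, a fraction of a percent
  of unique clonotypes), while the rest are shared sporadically.
* **Greater alpha- than beta-chain sharing**, via per-chain public
  fractions (defaults 0.06 for alpha, 0.025 for beta, mirroring the
  reported ordering of sharing percentages without claiming the exact
  values). Private clonotypes are generated uniformly (CDR3 lengths 10-16
  aa, residues uniform over the 20 amino acids, V/J labels uniform over
  per-chain catalogs) and rejected against collisions.
* **Age- and sex-linked clonal expansion at fixed sequencing depth.** A
  random 1% "chronic" subset of each repertoire's clonotypes has its counts
  multiplied by `exp(beta * age * s)`, with `beta = 0.05` per week and
  `s = 1.5` for males (`s = 1` otherwise); the resulting excess molecules
  are then removed from the non-chronic clones' spare molecules (those above
  each clone's first) by a multivariate hypergeometric draw, so the total
  molecule count and the number of unique clonotypes are exactly unchanged.
  Expansion saturates gracefully when the spare pool cannot cover it.

The fixed-depth construction is deliberate: sequencing depth is an
experimental variable, independent of clonal composition, so chronic
expansion should shift relative abundances rather than inflate the molecule
total. A simpler multiply-and-round-up mechanism makes depth grow with age,
which mechanically drags richness (unique/size) down with age — the opposite
of the flat-richness, falling-diversity signature this generator exists to
emulate. With the compositional mechanism, richness is age-invariant by
construction and Shannon/Simpson diversity declines with age, most steeply
in the sex carrying the multiplier, so the fitted age-by-sex interaction on
Shannon is negative — the qualitative pattern the covariate models are
validated against. Effect-size defaults were chosen once, during generator
design, to make that documented signature clearly expressed at cohort size
60; they are generator settings, not estimates of the wild-mouse process.

Metadata are drawn per mouse: sex Bernoulli(1/2), age uniform on 2-49
weeks, site from a two-site mixture (0.94/0.06). All randomness descends
from one master seed through labelled hash-derived sub-seeds; cohorts
written to disk are byte-identical across runs of the same config.

What the generator does **not** emulate: V(D)J recombination statistics,
thymic selection, CDR3 sequence similarity structure, lab-versus-wild
cohort contrasts, or site effects on repertoire composition. Passing tests
therefore demonstrate that the pipeline's estimators and models recover the
structure they assume — not that wild-mouse data satisfy those assumptions.

## Numerical choices and degenerate inputs

* Natural logarithms everywhere; diversity identities hold to 1e-12 on
  closed-form cases.
* Power-law MLE is a bounded scalar minimisation of the exact zeta
  likelihood on alpha in (1, 25]; degenerate inputs (all counts equal,
  fewer than 10 observations) are rejected.
* Bootstrap replicates that degenerate to a single repeated value are
  counted as extreme (conservative).
* Down-sampling requires `1 <= target <= size`; the empty repertoire is an
  error for every summary statistic.
* An all-equal off-diagonal sharing matrix yields an all-zero dissimilarity
  with a warning rather than an error.
* PCoA eigenvalues below `1e-8 * max|eig|` are treated as null axes.
* The pipeline is byte-deterministic given (config, inputs); the manifest
  echoes the config and per-stage row counts.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on synthetic data:
cohorts of 60 mice at 5000 unique clonotypes per repertoire for effect
recovery (50 replicates), 10^4 power-law draws for estimator recovery, 50
runs of 200 bootstrap replicates at n=500 for GoF calibration, and 10^4
replicate draws for the down-sampling distribution checks. These sizes were
chosen as the smallest at which the statistical claims are cleanly
testable; all scale linearly if increased.

## Known limitations

* Public-clonotype prevalence and sharing percentages depend on the
  generator's pool-popularity profile; only their qualitative ordering
  (alpha > beta, public fraction well below 1% of unique clonotypes) is
  calibrated.
* The gamma GLM's dispersion is estimated by Pearson chi-square over
  residual df; with heavy-tailed repertoire-size noise its standard errors
  are conservative.
* The sharing GLM treats pairs as independent observations (as is standard
  for this design); use the permutation option for dependence-robust
  p-values.
* `xmin` re-selection inside each bootstrap replicate makes the GoF p-value
  mildly conservative.
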