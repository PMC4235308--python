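# Methods

## Problem and model

`mirecur` infers miRNA–target interactions that *recur* across a panel of D
tumour cohorts from paired per-cohort matrices of gene expression, miRNA
expression, gene copy number (CN) and promoter DNA methylation (DM).
MicroRNAs predominantly repress their targets, so a genuine interaction
shows up as a negative association between miRNA and target expression once
the two major confounders of target expression — gene dosage and promoter
methylation — are adjusted for.

### Per-cohort evidence

For every (gene *i*, miRNA *k*) pair in cohort *d* we fit, by ordinary least
squares,

    y_i = β0 + β_cn · cn_i + β_dm · dm_i + β_mir · x_k + ε,  ε ~ N(0, σ²)

where `y` is log2 target expression, `x` log2 miRNA expression, and `cn`,
`dm` the gene's copy-number score and promoter beta value across the T
samples. The miRNA coefficient's t-statistic (T − 4 residual df) is mapped
to a z-score through z = Φ⁻¹(F_t(t; T−4)), computed on the log scale so
extreme tails do not underflow; |z| is capped at 8 (configurable), which
preserves ordering while keeping downstream density estimation on a finite
range. Under the null of no interaction, z ~ N(0, 1).

Zero-variance covariates are dropped with an adjusted df; samples with
missing values are dropped pairwise per regression. The per-cohort scorer
uses the Frisch–Waugh–Lovell decomposition (residualize y and all miRNA
profiles against [1, cn, dm] per gene), which is algebraically identical to
the full OLS fit and turns the M×N regressions into a handful of matrix
products per gene.

### Candidate filter

Pairs with z < 0 in at least ⌈0.75·D⌉ cohorts form the candidate set
(strictly negative; uncomputed cohorts never count). Everything downstream
operates on candidates only.

### Two-group decomposition (local false discovery rate)

Within each cohort the candidate z-scores are modelled as a two-group
mixture f(z) = p0·f0(z) + (1 − p0)·f1(z). The marginal f is estimated by
Lindsey's method: a histogram (default 120 bins over the data range) whose
counts are Poisson-regressed on a polynomial basis (default degree 7). The
null component f0 = N(μ0, s0) and null proportion p0 come from central
matching: a truncated-normal maximum-likelihood fit to the fraction of
z-scores nearest the histogram mode, with p0 the window's observed mass
divided by the fitted null mass there. locfdr(z) = min(1, p0·f0(z)/f(z)) is
the posterior probability of the null given z, and rearranging the mixture
identity gives the per-cohort component likelihoods that feed the EM:

    L0(z) = locfdr(z)·f(z)/p0        (z | no interaction)
    L1(z) = (1 − locfdr(z))·f(z)/(1 − p0)   (z | interaction)

Both are floored at 1e-12 so no configuration is ever annihilated, and p0
is capped at 1 − 1e-6 when forming L1.

Design notes made where the design was genuinely open:

* **Central window width.** The default window holds the central 75% of the
  z-scores. A Cramér–Rao computation for the truncated normal shows that on
  a central 50% window the standard error of s0 is ≥ 0.048 at n = 50,000
  for *any* estimator — too noisy for the tail ratios the EM consumes (a
  ±0.05 error in s0 moves the null density at z = −4 by a factor ~2.2). At
  75% (≈ ±1.15 s0) the bound drops to ~0.014. The window fraction is
  configurable (`central_mass`).
* **Truncated MLE rather than a log-quadratic fit.** Matching a quadratic
  to the smoothed log-density inherits curvature bias from the global
  polynomial when the non-null bump is prominent; fitting the raw central
  z-values by truncated-normal likelihood is unbiased in simulations and
  sits at the information bound.
* **Empirical vs theoretical null.** The candidate set is negatively skewed
  by construction, so the empirical null centred on the observed mode is the
  default; `mode="theoretical"` fixes f0 = N(0, 1) and matches only p0. When
  the central window of a tiny cohort cannot support the fit, the code falls
  back to the theoretical null automatically (recorded in the fit's `mode`).

### Recurrence EM

Each candidate pair carries a latent binary vector (t_1, …, t_D) of
per-cohort activity. Assuming the z's are conditionally independent given
the t's, a configuration's likelihood factorizes as Π_d (t_d ? L1_d : L0_d).
A single prior over all 2^D configurations is shared by all pairs,
initialized uniform (1/2^D), and fitted by EM:

* E-step: posterior(c) ∝ prior(c)·exp(Σ_d log L), normalized by
  log-sum-exp; the log-evidence per pair is the normalizer.
* M-step: prior(c) = mean posterior(c) over the candidate pairs (the
  averaging runs over the pairs that actually have likelihoods).
* Stop when the total log-likelihood (sum of per-pair log-evidence) rises
  by less than `tol` (default 1e-5, absolute; a relative option exists), or
  at `max_iter` (200) with `converged=False`.

The *recurrence posterior* of a pair is the posterior mass of the all-ones
configuration. Configurations are enumerated with cohort 1 as the
least-significant bit (all-ones = index 2^D − 1); the enumeration is part of
the serialized-prior contract. The E/M sweep streams over pairs in chunks
(configurable) so the (n_pairs × 2^D) block is never fully materialized; at
D = 12 the space has 4096 configurations and full enumeration is refused
above D = 20. The procedure is deterministic — no randomness anywhere.

### REC baseline

The rank-based recurrence score ranks, per (miRNA, cohort), the N genes by
*decreasing* t-statistic (midranks on ties), normalizes rr = r/N − 1/(2N)
(uniform on a lattice in (0,1) under the null), Fisher-combines
s = −2·Σ_d ln rr and refers s to χ²(2D). REC = log10 P(χ²_2D ≤ s), computed
through the log-scale regularized incomplete gamma with a series fallback
near s → 0; calls are positive when REC < −1 (strict). The rank direction
is the only one under which a more negative REC indicates recurrent
repression (most negative t → rank N → rr near 1 → s near 0); a flag flips
it. Degenerate rank vectors are clamped to [1/(4N), 1 − 1/(4N)] and flagged.

### Evaluation procedures

* Top-k overlap curves against reference pair sets (k = 2000…20000 step
  2000 by default) with a seeded shuffled-ranking baseline.
* One-sided Wilcoxon rank-sum / signed-rank location tests (scipy; exact
  for small samples).
* Upper-tail hypergeometric enrichment (scipy).
* Resampling gene-set enrichment: the statistic is the number of *distinct*
  gene-set genes among a signature's targets; the null redraws equally many
  interactions from the pool without replacement; p uses the add-one
  correction (1 + #{null ≥ obs})/(reps + 1). Production default 1e6 reps;
  tests use 1e4 or less. Because the count statistic is heavily discrete,
  these p-values are super-uniform (conservative), not uniform.
* Prognostic screen: per interaction and cohort, each member's expression
  is split at the sample mean (ties to "low"; constant vectors flagged),
  the two groups compared by the log-rank test (lifelines), and the
  interaction flagged in a cohort iff *both* members reach p < α (default
  0.1). Cohorts with fewer than 3 observed events are skipped. KM curves
  come from the product-limit estimator (lifelines-backed, verified against
  hand computations and an independent loop implementation in the tests).

## Synthetic compendium

The generator emulates the structure the inference assumes: per cohort,
miRNA expression and copy number are standard Gaussian, methylation betas
are Beta(2,2), and target expression is
β0 + β_cn·cn + β_dm·dm + Σ_planted β_mir·x + N(0, noise_sd), with matrices
emitted on the log2-like scale the regression operates on (so the
generative and inferential models coincide; the raw-scale preprocessing ops
are exercised on separate fixtures). Default conditions: D = 4 cohorts,
N = 300 genes, M = 30 miRNAs, T = 60 samples, 2% of pairs planted recurrent
(active in all cohorts), 2% cohort-specific (active in exactly one,
uniformly chosen), β_mir = −1, β_cn = 0.5, β_dm = −1, noise_sd = 1. The
cohort-specific effect size equals the recurrent one on purpose, so the
recurrence posterior — not effect size — is what separates the classes.
Survival tables are exponential with log-rate linear in chosen
(standardized) signature features, with independent Bernoulli censoring.

What the generator does *not* emulate: count-level sequencing noise
(negative binomial), tumour purity, batch structure, correlated miRNA
families, or realistic CN/DM marginals. Passing the planted-recovery tests
therefore shows the inferential machinery is correct under its own model
assumptions, not that real pan-cancer data would yield the same separation.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems chosen as
representative while keeping full runs in seconds-to-minutes: the default
planted compendium above (~3,000 candidates × 16 configurations in the EM),
10,000-pair pure-null panels for z calibration, 10,000 simulated Fisher
statistics for the REC null, and 500-replicate null panels for log-rank and
resampling p-values. Production-scale runs (millions of candidates, 4096
configurations) stream in chunks through the same code path.

Numerics: all likelihood products are log-space with log-sum-exp
normalization; t→z uses log CDFs with `ndtri_exp`; z capped at ±8 with a
flag; likelihood floor 1e-12; density floor 1e-300; posterior sums verified
to 1e-9; EM log-likelihood monotone within 1e-9 slack; recurrence tables
tie-break by gene then miRNA id for byte-reproducible output; feature
universes are intersected and ordered lexicographically.

## Known limitations

* The conditional-independence assumption across cohorts ignores shared
  germline copy-number structure and cross-cohort batch effects.
* The shared configuration prior is exchangeable over pairs; no structure
  over cohort subsets (e.g. tissue groupings) is modelled.
* The empirical-null fit assumes the central mode is null-dominated; under
  extreme signal fractions (>~50% non-null) central matching is biased.
* One miRNA per regression: co-targeting by multiple miRNAs inflates the
  residual and dilutes, but does not bias, single-miRNA coefficients.
* The χ²(2D) reference for REC assumes independent uniform ranks across
  cohorts and is approximate on the rank lattice.
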