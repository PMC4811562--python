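# Methods

## The experiment and its coding

A paired discrete choice experiment over six livelihood attributes:
drought grazing access (allowed / prohibited), cattle (0 / 40 / 100
head), conservancy involvement (none / half of a 150-acre holding for
9,000 KSh per month / all of it for 18,000 KSh), cultivation (none /
5 acres), small stock (0 / 80 / 200 head) and monthly wage (0 / 6,000 /
10,000 KSh). The full factorial holds 2·3·3·2·3·3 = 324 profiles and
324·323/2 = 52,326 unordered pairs of distinct profiles.

The model sees only coded differences between the two options of a pair
(option 2 minus option 1): continuous attributes are divided by a unit
scale chosen so coefficients are reported per 100 cattle, per 200 small
stock and per 10,000 KSh; each categorical attribute contributes one
dummy difference in {-1, 0, 1} per non-reference level (`cons150` codes
full leasing, `cons75` half leasing, against no involvement). The coded
column order is fixed: `access, cattle, cons150, cons75, cult, smlstk,
wage`. Choice tables carry raw (unscaled) differences; scaling happens
in panel assembly, so writing and re-reading data is lossless in exact
integers.

## Design search

`federov_select` runs the classic single-swap Fedorov exchange on the
coded difference vectors: random initial 16-subsets, best-improvement
swaps using the rank-one determinant update, termination at a local
optimum, best of `restarts` starts (default 100). The criterion is the
D-error `|X'X/n|^(-1/p)` with p = 7 and no intercept column; it is
invariant to row order and to swapping the options within a pair. Ties
are broken by lowest candidate enumeration index, and any instance with
at most 5,000 candidate subsets is solved by exhaustive enumeration, so
small problems are exactly optimal by construction. Blocking into two
blocks of eight maximizes the product of within-block information
determinants; with 6,435 distinct 8+8 partitions this step is always
exhaustive at the study size (larger instances fall back to a restarted
swap exchange).

Two deliberate choices deserve emphasis:

**Option-order assignment.** Because the D-error ignores row signs, its
optimum happily presents every pair in an orientation that leaves one
coded column constant (drought access always +1), which would confound
that attribute with the model's intercept — the "tendency to choose the
second option" — and leave Model 1 unidentified. After selection, the
package assigns option order within each pair by greedy sign flips
maximizing the determinant of the intercept-augmented information
matrix. This mirrors what survey practice does implicitly when option
order on choice cards is balanced, changes no pair and no D-error, and
makes all eight coefficients estimable.

**Criterion conventions.** Exact-design software in common use reports
the normalized information determinant `D = |X'X/N|^(1/k)` of a
*profile* model matrix in which every attribute is a factor with
treatment contrasts plus an intercept (k = 11 columns here). Published
design criteria for this experiment are on that scale (a 16-run search
on the 324-profile factorial attains D ≈ 0.226). The difference-coded
D-error used by `federov_select` cannot be compared with such values —
all its coded columns are bounded by 1, so that D-error is bounded
below by 1 (the achieved value is ≈ 1.17). The package therefore
exposes both: `d_error` for the paired difference design it optimizes,
and `reference_profile_criterion` for comparability with published
figures; any reported comparison states which convention it uses.

## Estimation

The hierarchical mixed logit is

    y_ir ~ Bernoulli(logistic(b_i · x_ir))
    b_i  ~ MVN(m + G z_i, diag(s) R diag(s))

with K = 8 coefficients (intercept plus seven attribute columns) and
respondent covariates z_i entering only through the coefficient means.
Count-like covariates (land, settlement years, household size, building
counts) are centred and divided by two sample standard deviations so
their loadings are visually comparable with the binary covariates'
loadings; the transform is stored with the fit and applied when a group
profile is evaluated. s and R are common across groups.

Priors are weakly informative and configurable: Normal(0, 5) on m and
G, half-Normal(0, 2.5) on s, LKJ(eta = 2) on R. The original analysis's
exact prior specification is not public, so numerical equality with the
published posterior summaries is not guaranteed; agreement is assessed
at the level of credible-interval overlap.

Sampling uses a No-U-Turn sampler (multinomial variant, max tree depth
10) with dual-averaging step-size adaptation (target acceptance 0.8)
and a diagonal mass matrix estimated in expanding warmup windows. The
model is non-centered: b_i = m + G z_i + diag(s) L u_i with u_i
standard normal and L the Cholesky factor of R, parameterized through
canonical partial correlations z = tanh(y). Under the LKJ prior those
partial correlations are independent shifted-Beta variables (tree level
k has Beta(eta + (K-1-k)/2) on (-1, 1)), which gives a closed-form
unconstrained log density; all gradients are analytic and are verified
against finite differences in the test suite. Default 4 chains of 1,000
warmup + 1,000 sampling iterations; a seed is mandatory and chains are
seeded by SeedSequence spawning. Convergence is summarized by classic
split-Rhat and Geyer initial-sequence effective sample size; a fit with
any population-level split-Rhat above 1.01 is flagged (summaries are
still produced, with a warning).

Numerical choices: the Bernoulli log likelihood is computed as
y·eta − log(1 + exp(eta)) via `logaddexp` and is stable to |eta| ≈ 500;
1 − z² terms in the correlation transform are floored at 1e-12; a
singular information matrix yields a +inf D-error sentinel rather than
an exception; s ≤ 0 or a non-positive-definite R yield a −inf prior
sentinel.

## Posterior summaries

All derived quantities are computed per draw and then summarized, so
their intervals are genuine posterior intervals: the cattle substitution
rate of attribute a at covariate profile z is
kappa_a / (kappa_cattle/100) with kappa = m + G z evaluated per draw
(optionally dividing kappa_a by its own unit scale for per-head or
per-unit rates); the share of individuals valuing an attribute
negatively is 100·Phi(−kappa/s_k); coefficient correlations are draws of
R entries. A plug-in computation on posterior means (e.g. 1.11 /
(1.86/100) = 59.68 cattle) therefore differs slightly from the
posterior-mean ratio (≈ 60 in a full fit). Equal-tailed intervals use
linear-interpolation quantiles; HPD intervals take the shortest window
of ceil(level·n) sorted draws (ties: lowest window) and are used for
interval plots. If more than 1% of draws put the cattle coefficient
within 1e-6 of zero the ratio summary carries an instability warning.

## Synthetic data and what it shows

The generator reproduces the study's structure: n respondents (default
388), each assigned one of the two design blocks (alternating by index
by default) and answering its eight situations, with b_i drawn from the
truth's multivariate normal and choices from the logistic model. The
default truth sets m and s to the fitted Model 1 values and the three
large reported cattle correlations (0.85 with small stock, 0.64 with
cultivation, 0.57 with half-leasing), completed to a positive-definite
R by treating them as loadings on a single latent factor. Covariates
are simple parametric defaults (independent Bernoulli(0.5) sex and
membership, gamma land, Poisson building counts, ...), chosen for
identifiability rather than demographic realism — passing recovery
tests therefore demonstrates correctness of design, estimation and
summaries under the model's own assumptions, not robustness to real
survey features such as village clustering, item non-response,
lexicographic choice behaviour or scale heterogeneity, none of which
are simulated.

Parameter recovery at the study's size (n = 388, two blocks of eight)
recovers every component of m within its 95% interval. At much smaller
samples (n ≈ 100) the utility scale of a mixed logit with eight
correlated random coefficients is only weakly identified: posterior
means of m and s inflate jointly (roughly preserving their ratios) and
interval coverage of m degrades. This is a property of the model and
sample size, not of the sampler — pinning (s, R) at the truth, or
shrinking s to 0.01, recovers m and matches an independent
maximum-likelihood logistic fit, respectively. Recovery experiments in
the tests use n = 388 with 5 replicates and 2 chains of 800 warmup +
500 sampling iterations; the full 20-replicate experiment is a few
hours of CPU and is exposed as `recovery_experiment` for offline runs.

## Known limitations

- Two alternatives per situation only; no opt-out option, labelled
  alternatives, or best-worst scaling.
- Preference-space parameterization only (no willingness-to-pay-space
  estimation, no maximum simulated likelihood).
- Covariates shift coefficient means only; s and R do not vary between
  groups.
- The design search does not use prior parameter information (no
  Bayesian D-error) and imposes no level-balance or attribute-overlap
  constraints beyond what the criterion induces.
- Group profiles for scaled covariates are interpreted through the
  centring recorded at fit time; profiles far outside the observed
  covariate range extrapolate linearly.
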