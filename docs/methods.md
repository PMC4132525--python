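# Methods

`mokkensep` implements nonparametric item response theory (Mokken)
scale construction for household socioeconomic position (SEP) from
dichotomous asset-ownership items, together with the standard
alternative — a principal component analysis of the polychoric
correlation matrix — and the machinery to compare both against a
continuous expenditure measure. This note records the models, the
tuning constants, the numerical choices, and what the synthetic data
do and do not establish.

## The measurement model

Household SEP is treated as a scalar latent trait θ. Each asset item
i has an item response function P_i(θ) — the probability that a
household at trait level θ owns asset i. The monotone homogeneity
model (MMH) assumes a single dominant trait, local independence of
items given θ, and monotone non-decreasing P_i. Under MMH the
unweighted sum score orders households on θ. The double monotonicity
model (DMM) additionally assumes non-intersecting response functions
(invariant item ordering, IIO): the difficulty order of the items is
the same at every trait level, so the items themselves can be ranked
from "easy" (a bucket) to "hard" (a dishwasher).

### Loevinger's H

For an item pair, call the less popular item *harder* (ties go to the
lower column index). A Guttman error is a household owning the harder
item but not the easier one. With F_ij observed errors and
E_ij = n·p_h·(1−p_e) errors expected under independence,

    H_ij = 1 − F_ij / E_ij = cov(X_i, X_j) / (p_h (1 − p_e)),

the two forms being algebraically identical when covariances use the
1/n denominator (the test suite asserts agreement to 1e-12 against a
row-by-row counting oracle). Item and scale coefficients H_i and H
are one minus ratios of the corresponding summed F and E, so each H_i
lies between the extreme H_ij of its pairs. H computed on the
*transposed* matrix (households as pseudo-items; constant household
rows dropped) summarises how accurately the item ordering holds
across households. Conventional interpretation bands are used:
below .3 unscalable, .3–.4 weak, .4–.5 medium, above .5 strong.

Standard errors of H_i are nonparametric bootstrap (households
resampled with replacement; default 1000 replicates, seeded).
Replicates in which an item becomes constant are dropped and logged;
more than 10% dropped triggers a warning. A closed-form delta-method
SE would also have been defensible; the bootstrap was chosen because
it extends unchanged to any functional of the response matrix.

### Automated item selection (AISP)

Classic sequential bottom-up selection. A scale is seeded with the
pair maximising H_ij among pairs with H_ij ≥ c whose positivity is
statistically significant; items are then added one at a time — each
must have significantly positive H_ij with every current member and
within-scale H_i ≥ c — choosing the candidate that maximises the
resulting scale H (ties: higher H_i, then lower column index). Closed
scales are removed from the pool and the procedure restarts; leftover
items are unscalable. Defaults: c = .3 (the conventional lower bound),
α = .05 one-sided.

Positivity of H_ij is tested by a seeded bootstrap percentile test:
reject when the α-quantile of the bootstrap distribution of H_ij
exceeds zero. Because a pair statistic depends on the data only
through the 2×2 pattern counts, the bootstrap is drawn directly as a
multinomial over the four patterns (500 replicates by default), which
makes the full pairwise scan cheap even for 17-item pools. No
multiplicity correction is applied across pairs; the number of tests
performed is logged so users can impose their own.

A practical consequence worth knowing: for very rare items (popularity
well under 1%) the pairwise counts are tiny and the positivity test is
near its boundary, so whether such an item enters the main scale can
vary over replications of the same generating process. This mirrors
the behaviour of AISP on real asset data, where sub-1% luxury items
are the least stable members of a wealth scale.

### Restscore model checks

Monotonicity: for each item, households are grouped by the rest score
(sum over the other scale items); the item's ownership proportion is
compared across all ordered group pairs. IIO: for each item pair
(harder vs easier by overall popularity), proportions are compared
within rest-score groups that exclude both items. A *violation* is a
reversal exceeding `minvi` (default .03); it is *critical* when also
significant at `alpha` (default .05) — a one-sided pooled
two-proportion z-test for monotonicity, and for IIO an exact one-sided
sign test on the group's discordant households (the households owning
exactly one of the two items), which respects the pairing of the two
items on the same households. The magnitude-plus-significance
definition of "critical" is a package choice and both constants are
configurable and logged.

Rest-score groups merge adjacent rest-score values from low to high
until each group reaches `minsize` (default n/10 for n ≥ 500, n/5
otherwise, floor 50); an undersized tail is folded into the last
group, and n < 2·minsize degenerates to a single group with a warning.

Iterative IIO removal drops the item with the most critical violations
(ties: larger maximum violation, then lower within-scale H_i, then
lower index), re-checks, and stops when no critical violations remain
or the scale would shrink below three items. Termination within k−2
iterations is guaranteed and tested. On equal-discrimination synthetic
banks (IIO true) the loop removes nothing in ≥ 18/20 seeds; with one
strongly crossing item injected (discrimination 6 vs 1) it removes
exactly that item in ≥ 18/20 seeds — the empirical type-I/power
contract asserted in the acceptance suite.

## The PCA wealth index

Dichotomous items violate the multivariate-normality premise of
ordinary PCA, so the PCA is run on the tetrachoric (2×2 polychoric)
correlation matrix: each pairwise correlation is the latent
bivariate-normal correlation estimated in two steps — thresholds from
the inverse normal of the margins, then ρ by maximising the 2×2
multinomial likelihood under bivariate-normal orthant probabilities.
The bivariate normal CDF is evaluated with Owen's T function, which is
deterministic and accurate to well below the 1e-4 tolerance asserted
against the arcsin closed form at zero thresholds
(P(1,1) = ¼ + arcsin ρ / 2π). A zero cell triggers a +0.5 continuity
correction on all four cells (logged); a zero margin is an error; |ρ|
is clipped at 1 − 1e-6 and flagged. The assembled matrix is
symmetrised and, if any eigenvalue falls below 1e-8, repaired by
eigenvalue clipping and rescaling to unit diagonal (logged).

The index is the first principal component, sign-normalised so the
loading sum is positive (higher = wealthier), with variance
proportions eigenvalue/k. Households are scored with Filmer–Pritchett
standardisation, score_h = Σ_i w_i (x_hi − p_i)/√(p_i(1−p_i)); items
could alternatively be left unstandardised, and this choice is a known
replication caveat for comparisons with other software.

## Quintiles

With discrete sum scores, exact fifths are impossible. The boundary
for quintile q is the smallest score whose empirical CDF reaches q/5
(evaluated in exact integer arithmetic), and all households sharing a
score share a quintile — so quintile sizes are only approximately
equal and a heavily tied bottom score can absorb several nominal
quintiles. Assignment is monotone in the score by construction.

## Reliability and comparison

Cronbach's alpha is computed on weighted items y_i = w_i x_i (unit
weights for the Mokken scale, first-component loadings for the PCA
scales), with sample variances (n−1 denominator). The 95% CI uses the
Feldt method: (1 − α̂) is treated as a scaled F with (n−1, (n−1)(k−1))
degrees of freedom. The CI method is reported in the output metadata
because other interval constructions exist; n and k are reported so
they can be swapped in.

Expenditure is natural-log transformed before comparison (the log
base is a package choice, flagged in output metadata; correlations are
invariant to it). The comparison report gives Pearson r between
continuous scores, Spearman r (average ranks, as quintile labels are
heavily tied) between quintile labels, and per-quintile log-expenditure
summaries (n, quartiles, median) for boxplot-style display; empty
quintiles appear with n = 0 rather than being dropped.

## The synthetic-data generator

Responses follow a two-parameter logistic (2PL) model,
P_i(θ) = logistic(a_i(θ − b_i)), θ ~ N(0,1) — the simplest monotone
family satisfying MMH, with the useful property that equal
discriminations give non-intersecting curves (IIO true by
construction), providing clean negative controls. Expenditure is
log-normal with a trait loading, log E = μ + λθ + σε, with defaults
μ = 7, λ = 0.75, σ = 1, giving corr(log E, θ) = λ/√(λ²+σ²) = 0.6,
a moderate association of the kind observed between asset indices and
expenditure in household surveys.

The default 17-item survey emulates the structure of a national asset
module: 12 items on the dominant trait (a = 2) with difficulties
calibrated by quadrature so marginal popularities span ~90% down to
0.34%; a two-item secondary cluster (bucket, agricultural machine) on
a second trait correlated 0.4 with the main one — close enough to be
real structure, far enough that the pair forms its own scale; and
three near-flat noise items (a = 0.3). Default sample size is 3,810
households. Difficulty calibration inverts the Gauss–Hermite marginal
popularity with Brent's method, and the empirical popularities are
tested against an independent adaptive-quadrature oracle.

Violation injectors append, without touching the base items, either a
unimodal item (Gaussian bump in θ scaled to a 0.9 maximum — the
"middle-SEP asset" that breaks monotonicity) or a monotone 2PL item
whose discrimination must differ at least threefold from every base
item so its response curve genuinely crosses the others.

What the generator does *not* emulate: survey design (strata,
clusters, weights), missing data (the analysis pipeline is
complete-case, and missingness is generated by the user's data, not
by the simulator), local dependence between items beyond the secondary
trait, and non-normal trait distributions. Passing tests on this
generator therefore establish internal correctness and the statistical
operating characteristics of the procedures under a well-specified
IRT world, not robustness to the messiness of real survey microdata.

## Problem sizes and numerical notes

Simulation-based tests use 1,200–5,000 households and 2–17 items, with
10–200 replicate seeds per property — sizes at which the Monte-Carlo
error of each asserted quantity is an order of magnitude below its
tolerance. All randomness flows through seeded NumPy generators
(per-pair bootstrap seeds are derived from the config seed via
`SeedSequence`, keeping runs deterministic regardless of evaluation
order), and the pipeline is idempotent: two runs from the same config
agree byte-for-byte except for the provenance timestamp.

Degenerate inputs are rejected early and loudly: constant items at
response-matrix construction, constant households at transposition,
zero margins in tetrachoric tables, constant scores at quintile
assignment, zero total variance in alpha. Tie rules are fixed and
documented (harder item of an equal-popularity pair is the lower
index; AISP candidate ties go to higher H_i then lower index; removal
ties to larger violation then lower H_i then lower index) so that
every result is reproducible to the bit.

## Known limitations

- Polytomous items are out of scope; everything is dichotomous (counts
  must be thresholded via the config's dichotomisation rules).
- The AISP is the classic greedy procedure; it does not search for a
  globally optimal partition.
- Bootstrap SEs for H_i and the bootstrap positivity test are
  approximate for very rare items (few owners), where their sampling
  distributions are strongly discrete.
- The "critical violation" criterion (magnitude + significance) and
  the restscore grouping constants are conventions, not identities;
  results near the thresholds depend on them.
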