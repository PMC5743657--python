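# Methods

## Statistical model

Each observation is one leaf pair from a nested canopy design: quadrat
(plot), tree individual nested in quadrat, height class (`a`: base–2.5 m,
`b`: above 2.5 m) and horizontal position (`E` external / `I` internal),
with a random azimuthal exposure label. Trait values are analysed one trait
at a time on the Euclidean scale, so the permutational ANOVA reduces to
classical sums of squares with permutation-based inference.

All factors are treated as fixed. The model contains eleven terms: the four
main effects and the quadrat/individual interactions with the two canopy
factors, up to the three-way terms. Each term's model subspace is the span
of its cell indicators orthogonalized against all marginal (ancestor) terms
— nesting is therefore exact: `individual(quadrat)` contributes only the
31 within-quadrat contrasts, and removing `quadrat` from a reduced model
removes genuine quadrat directions even though the individual indicators
span them. Two decompositions are available:

- **sequential** (default): extra SS in the model order listed above. This
  is the default because the design is unbalanced (5/17/12 individuals per
  quadrat), so the decomposition depends on order and the conventional
  presentation order is the stable choice;
- **partial**: extra SS of each term given all other terms.

On balanced designs the two coincide (tested). Variance "explained" is
reported as the SS ratio SS_term/SS_total × 100 — a descriptive share of
observed variation, *not* a REML variance component. A grouping helper sums
shares into canopy-related terms (anything touching `h_class` or
`position`) versus plot/individual terms.

The pseudo-F of every term uses the residual mean square as denominator.
Significance comes from permutation of residuals under the reduced model
(Freedman–Lane): for term T, the model with all terms but T is fitted, its
residuals are permuted as whole observations and added back to the reduced
fit, and the extra-SS F of T is recomputed. Observed and permuted statistics
use this same extra-SS form, which equals the sequential F on balanced
designs. The p-value uses the add-one convention
p = (1 + #{F* ≥ F}) / (1 + n_perm); an exhaustive mode enumerates all
permutations for n ≤ 9 (used by the oracle tests). Defaults: 999
permutations, α = .05. Permutation exchanges individual observations; no
restricted/whole-plot scheme is applied, matching the
residuals-under-reduced-model description the analysis follows.

## Synthetic-data generator

The generator emulates the field campaign the pipeline was built around:
3 quadrats with (5, 17, 12) trees, 3 leaf pairs in each of the four
(height × position) strata, hence 12 per tree and 408 in total. Azimuth
labels are drawn uniformly on [0°, 360°) and binned E (45, 135], S (135,
225], W (225, 315], N otherwise; the measure-zero bin edges go to the
counter-clockwise neighbour.

Trait values follow y = grand_mean + Σ term effects + residual. Per-trait
defaults (means and SDs in trait units):

| trait | grand mean | total SD | non-residual fractions |
|---|---|---|---|
| sla | 8.02 mm²/mg | 0.96 | quadrat .012, h_class .185, position .026, individual .150 |
| pi | 3.29 −MPa | 1.01 | quadrat .039, h_class .014, position .026, individual .222, quadrat:position .024, h_class:position .010 |

The fractions are the SS shares of the terms with clear support in holm-oak
canopy data (main effects for both traits plus the two interactions listed
for π); the remainder is residual. Terms without clear support default to
zero but are fully configurable, as is every mean/SD/fraction.

Two sampling modes:

- `empirical=True` (default): each term's realized effect vector is
  orthogonalized against all preceding model terms and rescaled so its SS
  is exactly fraction × SD² × (N − 1); the residual is orthogonalized
  against the full model span and rescaled likewise. This is the
  `mvrnorm(empirical = TRUE)` convention: a sequential ANOVA on such data
  returns the configured percentages exactly, which is what makes the
  parameter-recovery tests sharp. The conditioning means the draw is not an
  i.i.d. sample from the implied population.
- `empirical=False`: level effects are i.i.d. Gaussian with variance
  fraction × SD². This is the honest sampling model and the one used for
  null-calibration (type-I error) testing, where the empirical mode's
  orthogonality would be unfaithful. Note that SS shares of few-level
  factors are then biased low by (L−1)/L and seed-noisy; recovery checks in
  this mode need averaging over seeds.

What the generator does **not** emulate: spatial autocorrelation within or
between crowns, non-Gaussian trait distributions (field SLA is typically
right-skewed), measurement error structure, missing leaves, or any
trait–trait dependence beyond an optional residual correlation (default 0).
Passing tests therefore demonstrate correctness of the *machinery* under
the stated variance structure, not robustness to those features of real
data. Gaussian tails can also produce occasional non-positive π values at
the default mean/SD; input validation enforces positivity only when reading
external files.

## Precision curve and flex point

For each n in the grid (default 2 … N; n = 1 is excluded with a warning
since a single leaf has no SE), replicates draw n leaves without
replacement; each scores SE = SD/√n and CV = SD/mean, and the curve stores
arithmetic means over replicates (4999 by default). No finite-population
correction is applied. The broken line y = β₀ + β₁n + β₂(n − ψ)₊ is fitted
to the mean curve (not to the replicate cloud): an exhaustive grid search
over interior grid values initializes ψ at the global RSS minimizer among
candidates, then iterative linearization (refit with the gap column
−1{n > ψ} and update ψ by the ratio of its coefficient to β₂) polishes it;
convergence at |Δψ| < 1e-8, cap 100 iterations. Because the broken line
nests the straight line at any fixed ψ, the two-segment RSS never exceeds
the single-line RSS; if it does not improve on it by more than 1e-10 of the
response's total SS the problem is flagged non-identifiable
(`converged=False`). The flex value SE_min = β₀ + β₁ψ is clamped at zero.
SE_min defines the precision threshold downstream; a CV flex point is
available the same way but is not part of the default screening.

The fitted ψ is the least-squares breakpoint of the whole curve; on a
smooth SD/√n-shaped curve sampled over a wide n range it is *not* a sharp
feature of the data, and its location (and hence SE_min) depends on the
grid extent. That sensitivity is inherent to the broken-line summary.

## Strategy simulation

Sampling is multistage and without replacement. Stage 1 selects
individuals: uniformly anywhere, or a fixed per-quadrat quota split as
equally as possible with remainders to quadrats in label order. Stage 2
selects leaves within each chosen tree: uniformly among eligible leaves, or
stratified over the allowed strata with remainders in the fixed order
(a,E), (a,I), (b,E), (b,I). A strategy may restrict eligibility to external
strata (sun-leaf protocols) or the upper-external stratum alone. Requested
sizes exceeding a quota or a stratum's capacity raise an infeasibility
error naming the binding constraint; on a grid run these become recorded
"skipped" cells rather than failures. The upper-external protocols hold
only 3 leaves per tree, so their 5×5 / 10×4 preset sizes are infeasible by
construction on the standard design and those strategies screen out with
reason "no feasible sizes".

Per replicate the trait mean, SE = pooled SD/√(total leaves) and CV are
recorded; per-cell summaries are replicate means. Each grid cell draws its
randomness from a substream keyed by (master seed, strategy name CRC,
size), so any cell can be reproduced in isolation. The leaf-level SE
convention matches the precision curve; it understates the uncertainty of
designs concentrating many leaves in few trees when between-tree variance
is present (see Limitations).

## Selection rules

Whole-data reference statistics use the t-based CI, mean ± t(N−1, .975)·SD/√N
at level .95 by default. Screening aggregates each strategy's per-size
means and SEs over its feasible size grid by the median (flag for mean);
a strategy is admissible iff, for *every* trait, the aggregated mean lies
in the closed CI and the aggregated SE ≤ SE_min. Among admissible
strategies, the most accurate — lowest median summed standardized deviation
S — is selected, mirroring the accuracy-first narrative of the protocol the
pipeline operationalizes. Within it:

- **minimum size**: the size with fewest total leaves whose per-size means
  are inside the CI and per-size SEs ≤ SE_min for all traits; ties go to
  fewer individuals, then lower ΣS;
- **optimal size**: ordering admissible sizes by total leaves, the size
  with the largest one-step decrease in ΣS; ties to the earlier (cheaper)
  size. A single admissible size is both minimum and optimal.

S sums over traits without weights (configurable in principle by operating
on the returned S table). The audit trail records the admissible set, the
strategy ranking and both rule applications so every decision is
recomputable from the stored summaries. With no admissible strategy the
result says so explicitly rather than guessing.

The largest-drop rule is a deterministic reading of "the most significant
drop of summed S"; when many admissible sizes have nearly equal S, the drop
location is dominated by Monte-Carlo noise in the cell means, so the chosen
optimum stabilizes only as replicates grow.

## Numerical choices

- Rank decisions in the projection bases use an SVD cutoff of
  1e-9 × max(N, 1) × leading singular value; a term with zero estimable
  df raises an aliasing error naming the term.
- Negative SS from floating-point cancellation are clamped at 0; permuted
  F comparisons use a 1e-12 relative tolerance on ties.
- Constant responses yield all-zero SS, pseudo-F reported as NaN and
  permutation p = 1.
- Trait values are written with 12 significant digits; round trips change
  them by < 1e-9.
- Per-cell seeds combine the master seed, a CRC-32 of the strategy name and
  the size into a `SeedSequence`, keeping streams independent and
  reproducible.

## Problem sizes used in checks

The automated checks run the permutation null at a reduced design (10 trees
× 12 leaves, 199 permutations, 1000 simulated datasets), parameter recovery
at the full 408-leaf design over 20 seeds, and precision-curve validation
at 4999 replicates; the acceptance script uses 1999 precision replicates,
499 strategy replicates per cell and 999 permutations. These sizes keep the
full verification loop fast while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- SS-ratio shares are descriptive; they are not variance components and
  will not match REML estimates on unbalanced data.
- The leaf-level SE convention ignores the design effect of clustering
  leaves within trees; a few-tree/many-leaf design can look "precise" while
  its replicate means still vary with the tree draw. The accuracy screen
  (CI membership of the mean of replicate means) does not catch this
  either, because random tree selection is unbiased. Interpreting the
  minimum size therefore requires the S table, not the SE alone.
- Strategy-level screening pools sizes by the median, so a strategy that is
  only adequate at large sizes can screen in (and vice versa); per-size
  admissibility is re-checked in the size-selection step.
- The breakpoint model fits one flex point; curves with several regimes are
  summarized by whichever single break minimizes RSS.
- Exhaustive permutation enumeration is limited to 9 observations;
  beyond that only sampled permutations are available.
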