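# Methods

## Depth model

Soil is sampled in contiguous half-open increments [top, bottom) in cm,
starting at 0. A *column* 0–d is the cumulative interval [0, d); d must
coincide with an increment boundary. Column values are thickness-weighted
means of increment values, so a constant profile is preserved and every
column value lies within the range of its contributing increments
(convexity). Soil organic carbon (SOC) stocks are per-area quantities and
are summed, not averaged: per increment the stock term is

    Depth_i [m] × (Ct/10) × (BD/1000) × (1 − CM/100) / 100

with Ct the organic-carbon concentration (mass-%), BD bulk density
(g cm⁻³) and CM the coarse-material volume fraction (%). This expression is
implemented literally as the default (`soc_formula: as_printed`) even though
its units do not produce conventional t ha⁻¹ magnitudes; the conventional
formula `Depth_i[cm] × BD × Ct × (1 − CM/100)` is available as
`soc_formula: conventional`. Column stocks are non-decreasing in depth and
exactly additive over a depth split — both are tested invariants.

Missing increment values are handled complete-case per (plot, property): a
plot missing any weighted increment is excluded from that property's column
with a logged warning. No imputation is attempted.

## Response variables

Per plot and vegetation layer (herb ≤ 1 m, tree > 1 m): species richness S
(count of species with positive abundance), Shannon H = −Σ p_i log p_i with
natural logarithm, evenness E = H/log S (undefined for S < 2; the log base
cancels here, and `log_base` is configurable), Faith's phylogenetic
diversity, and productivity. PD is root-inclusive by default (sum of branch
lengths of the minimal subtree connecting the plot's species to the root, so
a single species scores its root-to-tip path); `pd_root: exclude` switches to
the MRCA-rooted convention. Long-branch taxa can be excluded by name before
scoring. Basal area uses a strict DBH > 10 cm threshold, area π(DBH/200)² in
m². Herb biomass and stand age are measured inputs, not computed.

## Age correction

Each response is regressed by OLS on (1, log age) separately per layer;
downstream models use the residuals. Residuals sum to zero and are orthogonal
to log(age) to 1e-10 (tested). The age model's adjusted R² is reported per
response; predictors are deliberately not age-corrected — only the responses
carry a stand-age signal by design.

## Collinearity filter

Spearman rank correlations (mid-ranks for ties) among all candidate
predictors are computed on a configurable reference column (default 0–50 cm,
the broadest — the choice of reference column is not identified by the
procedure itself, so it is a configuration, not an inference). While any pair
exceeds the threshold (|r| > 0.7, strict), the member with the largest mean
|r| against the remaining variables is dropped, alphabetically later name on
ties. The rule is deterministic and order-independent; an explicit drop-list
can replace it to reproduce a fixed published exclusion set, and a keep-list
protects variables (a keep-list that itself violates the threshold is an
error, not silently accepted).

## Model selection

Gaussian linear models with intercept and main effects only. The criterion is
AICc with k = p + 2 parameters (intercept, p slopes, error variance) and
log-likelihood evaluated at the ML variance rss/n; AIC is used for the
species-richness responses, where the AICc penalty admits only intercept
models at n = 27. Subsets larger than n − 4 are never considered, keeping the
AICc correction finite with margin.

Search is exhaustive (provably optimal, ties broken toward fewer predictors
then lexicographic order) when the candidate count is at most 15; beyond
that a seeded genetic algorithm over subset-indicator bitstrings takes over
(tournament selection, uniform crossover, per-bit mutation 0.05, elitism 2,
population 40, 60 generations). Subset evaluation goes through precomputed
Gram matrices (one small symmetric solve per subset), which keeps the full
6 × 10 grid at a few seconds. The GA is deterministic under its seed; on
instances small enough to enumerate it matches the exhaustive optimum in
≥ 95% of seeded runs (tested at p = 10).

## Importance partitioning

Sequential (Type I) ANOVA sums of squares, entering terms in the fixed order
stable → dynamic → terrain, alphabetical within group. The decomposition
identity Σ term-SS + residual-SS = total-SS holds by construction and is
asserted to 1e-9 relative. Group importance is each group's share of the
summed *predictor* SS (the residual is excluded, so shares total 100%);
intercept-only models report undefined (NaN) importance rather than zero.
Because Type I SS depend on entry order for correlated predictors, an
order-averaged mode (`importance_order: averaged`) computes the mean over all
permutations of the selected terms, exact up to 8 predictors.

Depth trends use Kendall's tau-b (tie-corrected) between column depth and
importance, per response and pooled per layer; scipy's implementation
supplies exact p-values for small tie-free series and the normal
approximation otherwise.

## Critical depth extraction

Each fitted model contributes the point (column lower boundary in cm,
adjusted R²; `r2_kind: plain` switches to R²). The primary smoother is local
polynomial regression of degree 2 with tricube weights over a window holding
a `span` fraction of the points; span = 1 (the default) places every point in
every window, making the fit exact on quadratics — verified to machine
precision and against an independent weighted-normal-equations oracle. No
robustness iterations are applied. A global cubic polynomial is the
alternative smoother; both are always computed and reported side by side.
The critical depth is the argmax of the fitted curve over a 0.1 cm grid on
[min depth, max depth] — fine enough that discretization error is negligible
against the cm-scale answer — with ties resolved to the smallest depth and a
boundary flag raised when the argmax is an endpoint (the true maximum may lie
outside the sampled range). Curves are fitted per layer, pooled over both
layers, and per individual response (curves with fewer than four distinct
depths are skipped with a warning).

## Synthetic data generator

The generator emulates the structure of a 27-plot subtropical forest soil
survey with a known truth, not any particular site's values.

* **Soil.** Six study increments. Each *primary* dynamic property has a
  plot-level biotic signal (idiosyncratic effect, SD 0.6 of the property
  scale, plus a loading on one shared latent plot factor, |loading| in
  0.3–0.9) that decays exponentially with increment midpoint depth (rates
  spread over 0.06–0.2 cm⁻¹), plus increment-level measurement noise (SD 0.12
  of scale) and a plot-level *geogenic* component whose amplitude follows
  1 − exp(−0.05 · (depth − 10 cm)⁺): negligible in the biotically
  homogenized topsoil and growing toward the parent material, carrying no
  biotic signal. This geogenic term is what makes deep cumulative columns
  genuinely diluted rather than merely noisier. Derived dynamic properties
  follow their laboratory definitions (pH KCl offset from pH H₂O, Nt from
  Ct and C:N, CECeff as the sum of ion equivalents, BS and EA as its base and
  acid fractions, SOC stocks from Ct/BD/CM), which builds in the strong
  cross-correlations a collinearity filter exists to prune. Stable
  properties are depth-invariant per plot; texture fractions share a
  plot-level coarseness factor and the silt/sand sums are literal sums.
  Values are clipped to physical ranges (positive concentrations, 0–100%
  fractions), mimicking detection limits.
* **Responses.** Ten responses (five per layer). Each is
  base + scale · (Σ_j β z(x_j) + β_age log age + ε), where x_j are the
  *generated* (noise-inclusive) aggregates of that response's active
  predictors over the true column (default 0–20 cm), z is a z-score, β = 1,
  ε is N(0, 1), and the per-response base/scale map the standardized effect
  onto field-realistic units without changing any correlation. Active sets
  default to two dynamic properties plus one stable or terrain covariate.
  log-age effects are confined to the tree layer (strong for productivity,
  negligible for richness), mirroring the empirical pattern that stand age
  drives tree-layer but not herb-layer variation. Because the responses are
  built from the noisy true-column aggregates, the true column is the
  exactly optimal depth by construction, and the attainable R² (~0.75 under
  the defaults, the "moderate noise" condition) is recorded in the truth
  object.
* **Determinism.** All draws come from one `numpy` generator seeded per
  dataset; identical (config, seed) pairs give bit-identical tables.

What the generator does *not* emulate: spatially explicit terrain, real
pedogenesis, compositional closure of texture beyond the shared factor,
integer-valued species counts in the direct-response mode, or any feedback
of vegetation on soil. Passing recovery tests therefore demonstrates that
the pipeline finds the depth structure it is pointed at, not that any
particular field system has that structure.

With these defaults the pooled critical depth lands within one increment
boundary of the truth in ~88% of seeds (measured over 50), exactly 100% in
the noiseless limit (response noise and age effects set to zero), and the
tree-layer dynamic-group importance declines with depth. The residual
failure mode is honest: with ~20 candidates and n = 27, best-subset search
overfits every column to adjusted R² ≈ 0.8, which occasionally flattens the
shallow end of the curve enough that the smoother's argmax drifts to the
boundary.

## Numerical choices and degenerate inputs

* Weights, SS identities and stock additivity are validated at 1e-12–1e-9.
* Rank-deficient model designs raise an error naming the aliased columns.
* An all-zero abundance vector, a single-species evenness, constant tree age
  and a constant Kendall series are all explicit errors or NaN reports —
  never silent zeros.
* Ties: average ranks in Spearman; tau-b tie correction in Kendall; smallest
  depth at argmax ties; fewer predictors, then lexicographic order, at
  criterion ties.
* Pipeline runs are deterministic end-to-end given inputs, config and seed;
  the run report echoes the config and seed so a report plus inputs fully
  determines the outputs.

## Known limitations

* The exhaustive/GA switch means very large candidate sets rely on a
  stochastic search; the GA's optimum is not guaranteed, only empirically
  calibrated on enumerable instances.
* Type I importance shares are order-dependent for correlated predictors;
  the canonical order is a convention, and the order-averaged mode is
  exponential in the subset size.
* No confidence interval accompanies the critical depth; the boundary flag
  is the only warning that the optimum may not be interior.
* The "span = 1, degree = 2" smoother is one concrete reading of
  loess-style parameters; other software's local-regression variants may
  differ in window and weight details.
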