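# Methods

This note documents the models implemented in `lueff`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Landscape units

Landscape units (LUs) are axis-aligned square cells (default side 1000 m)
anchored at the lower-left corner of the study polygon's bounding box.  A
cell is retained only if its intersection with the study polygon reaches
0.999 km² — the *clipped* area, not the nominal cell area, is tested
(configurable via `ScenarioConfig.min_area_km2`).  Retained cells carry
their clipped area; distances to point layers (water, heritage, peaks) are
measured from the cell centroid and capped at 20 km so point-free
landscapes stay bounded.

## Synthetic landscape generator

The generator emulates a temperate, forest-dominated cultural landscape.
Its defaults encode the regional conditions the package targets:

- **Composition.**  Each LU draws an archetype from a three-component
  mixture (forest / forested mosaic / agricultural-urban with weights
  0.3214, 0.4786, 0.2000).  The forest share follows a per-archetype Beta
  law (means 0.93, 0.65, 0.20); the weights solve the moment condition so
  the aggregate forest-share mean is exactly 0.65.  The non-forest
  remainder is split over a random subset of the other eight LULC classes
  (1 + Binomial(7, p) classes, p per archetype) by a Dirichlet draw, so the
  per-LU count of distinct classes varies realistically between 2 and 9.
- **Drivers.**  Population density and road density are lognormal
  (means ≈ 45 persons km⁻² and ≈ 1.9 km km⁻²); Natura 2000 share is
  Beta with mean 0.70; heritage/spring/peak point layers are homogeneous
  Poisson processes (0.6 / 0.15 / 0.066 points km⁻²).  Road density is
  coupled to landscape heterogeneity (the distinct-LULC count) through a
  Gaussian copula whose mixing weight is calibrated by bisection on the
  realized sample, so the configured Spearman correlation (default 0.5)
  holds despite heavy ties in the count variable.
- **Ground-truth couplings.**  Slope and elevation increase with forest
  share (defaults +22 percentage points of slope and +380 m per unit forest
  share): forests occupy terrain unsuited to agriculture.  Because forest
  and successional classes are cheap to manage while permanent cultures and
  field crops are expensive, these couplings transmit a positive
  slope→efficiency and a negative heterogeneity→efficiency effect that the
  end-to-end tests verify sign-wise.
- **Costs and carbon.**  The per-class management costs (€ ha⁻¹ yr⁻¹) and
  topsoil carbon densities (Mg C km⁻²) shipped in
  `src/lueff/data/default_costs.csv` are synthetic placeholders ordered so
  that forest management is cheap relative to intensive agriculture; only
  their ordering, not their absolute level, is load-bearing (the efficiency
  model is units-invariant).

Everything is drawn from a single `numpy` generator seeded from the config,
in a fixed order, so identical `(config, seed)` pairs reproduce the
landscape bit for bit.

**What the generator does not emulate:** spatial autocorrelation between
neighbouring cells (fields are drawn independently given the archetype),
real settlement geography, viewshed-based esthetics or photo-based
visitation (both enter as non-negative surrogate surfaces with the same
statistical role), and any particular country's cost accounting.  Passing
tests therefore demonstrate the correctness and statistical behaviour of
the pipeline, not the empirical values of any real region.

## Ecosystem-service indicators

Seventeen benefit-oriented proxies in three groups (2 regulating,
9 cultural, 6 provisioning).  Open choices made here:

- **Erosion control is inverse-coded** (default): the presence of
  erosion-control measures marks ecosystems whose intrinsic
  erosion-control potential is low, so the indicator is 1 − share.  The
  benefit orientation is available via a flag.
- **Recreation potential** is the unweighted mean of six sub-indicators
  (protected-area share, naturalness, water proximity, LULC richness,
  slope roughness, peak proximity), each min-max normalized over the
  current LU set.  A constant sub-indicator carries no contrast and is set
  to 1 for all units.
- **Touristic and esthetic services** use generator-supplied surrogate
  surfaces rather than visitation or viewshed models.
- Medicinal-plant gathering households are assigned directly per LU from
  population (37.9% of households at 2.5 persons each), not apportioned
  from settlement polygons.

## Normalization and the cost input

ES columns are rescaled by v′ = 100·(v − min)/(max − min), *then* exact
zeros (in ES outputs and the cost input) are replaced by 0.001 — the
conventional guard for frontier software that cannot handle zero data.  The
order matters: a raw zero maps to 0 and then to 0.001.  A constant column
is mapped to 100 everywhere with a loud warning rather than dropped,
preserving the fixed 17-output structure.  Column extremes are pinned to
exactly 0 and 100 to avoid float drift.

The single cost input is the share-weighted mean class cost with urban and
artificial areas excluded from both numerator and area total (shares are
renormalized over the non-urban classes).  A hypothetical fully urban LU
gets cost 0, which the zero-replacement rule turns into 0.001.  The cost
input is deliberately *not* min-max normalized: the efficiency model is
invariant to units, and keeping €/ha makes the input interpretable.

## CCR efficiency

Scores come from the multiplier-form linear program (constant returns to
scale): maximize the weighted output sum of the assessed unit subject to
the normalization Σ vᵢ x_ik = 1 and the frontier constraints for all units.
Under constant returns this score equals both the input- and
output-oriented radial technical efficiency, so the single θ ∈ (0, 1]
serves an output-oriented reading.  Numerical choices:

- Strict weight positivity (the non-Archimedean condition) is implemented
  as a lower bound ε = 1e-9 on the multipliers of the *unit-scaled*
  problem (below).  Original-scale weights stay strictly positive.
- Input and output columns are rescaled to unit maxima before solving.
  This is mathematically neutral (units invariance) and makes the solved
  LP literally identical under any column rescaling, so scores are stable
  to ~1e-12 rather than solver tolerance under unit changes.
- Ties with the frontier use tolerance 1e-6 (θ ≥ 1 − 1e-6 counts as
  efficient); the categorization average is the mean over *all* scores by
  default (mean over the inefficient subset available via flag).
- Peers are the units whose frontier constraint binds (slack < 1e-7) at
  the optimum.  With multiple optimal weight vectors any optimum is
  accepted; only θ is contract-bearing.
- An independent test oracle maximizes the same objective over a dense
  grid of output-weight directions (with nested local refinement, all
  evaluations feasible), converging to the LP optimum from below; it
  agrees with the LP to 1e-3 on random single-input instances.

## Group statistics

Landscape types follow the forest-share bands >85% (forest), 40–85%
(forested; the 0.85 boundary belongs here, since "forest" requires strictly
more than 85%), <40% (agricultural/urban).  Kruskal–Wallis H is
tie-corrected; the p-value uses the chi-square approximation on g − 1
degrees of freedom for n > 50 and a seeded 20 000-draw permutation
reference for smaller samples, where the chi-square approximation can err
by an order of magnitude more than Monte-Carlo noise.  The permutation draw
is canonicalized (sorted ranks, label-sorted group sizes) so results do not
depend on observation order.  Type–ES associations use Spearman rho against
binary type-membership indicators.

## Two-limit Tobit

The likelihood sums the Gaussian log-density over interior observations and
log normal-tail probabilities over observations at the limits (0 and 1),
evaluated with `log_ndtr` for stability.  Optimization is BFGS on
(β, log σ) with the analytic score, initialized from least squares; a fit
that fails to improve on the initializer raises.  Standard errors come from
the inverse observed information, with the Hessian obtained by central
differences of the analytic score on the (β, σ) scale; p-values are
two-sided normal.  The pseudo-R² is the squared Pearson correlation between
the linear predictor and the observed response.  Degenerate designs (rank
deficiency, all observations censored at one limit) raise informative
errors rather than returning estimates.  Coefficients are reported on the
latent scale.

## Problem sizes

The test suite and the acceptance script use seeded synthetic scenarios
sized for sharp statistical checks at desk scale: 600–625 LUs for
end-to-end runs (the scale of a ~720 km² study region), n = 2000 with 200
replicates for Tobit parameter recovery, 1000 fuzzed instances for the
efficiency-model invariants, and 20 000-draw permutation references for the
rank tests.

## Known limitations

- No spatial statistics (e.g. local spatial autocorrelation of scores) and
  no spatially correlated generator fields.
- Constant returns to scale only; no variable-returns model, slack-based
  measures, super-efficiency, bootstrap bias correction or temporal
  (Malmquist) extensions.
- One planar coordinate frame; no CRS handling or raster I/O.
- The Tobit second stage inherits the usual caveat that efficiency scores
  are estimated, not observed; alternative fractional-response models are
  out of scope.
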