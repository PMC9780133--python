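# Methods

`spraydry` implements an end-to-end workflow for predicting the volumetric
median particle size (D50, μm) of spray-dried amorphous solid dispersions
(SDDs) from formulation and process attributes, and for inverting that model
to propose "first to try" process parameters for a target D50. This note
documents the models, the synthetic study conditions, the numerical choices,
and what the test suite does and does not demonstrate.

## The prediction problem

One record is a spray lot: formulation (active loading, polymer type and
loading, solids content, solvent system), process parameters (inlet/outlet
temperature, drying-gas flow, solution-to-gas mass-flow ratio, atomization
pressure), the pressure-swirl nozzle used, the dryer scale (pilot PSD-1 vs
production PSD-2), and the measured D50. The workflow trains regressors to
map the encoded attributes to D50, with every evaluation grouped by active
pharmaceutical ingredient (API): all sprays of an API are on one side of any
train/validation/test boundary, because API-specific chemistry induces
within-API correlations that would otherwise leak into the score.

## Feature encoding

- **Composition**: one column per polymer and solvent seen in training,
  holding the component's weight percent (0 when absent). Unseen categories
  at predict time map to zeros in the known columns and are logged, never
  fatal.
- **Nozzle target encoding with additive smoothing**: nozzle identity is
  replaced by `lam * m_c + (1 - lam) * m_global` with
  `lam = 1 / (1 + exp(-(n - k) / f))`, where `m_c` is the nozzle's mean
  training D50 over `n` sprays and `m_global` the overall training mean.
  Defaults `k = 1`, `f = 3`. The encoding is refit inside every CV fold from
  that fold's fit rows only; this is the pipeline's main leakage surface and
  is covered by dedicated tests (permuting held-out D50 must leave held-out
  features bit-identical). Nozzles unseen in training fall back to the
  global mean — a first-class path, since new nozzles are routine.
- **Scale indicator**: PSD-2 = 1.
- **Min–max scaling** to the training range per column; constant columns map
  to 0; test rows are not clipped (extrapolation is signal).

An alternative encoding replaces (or supplements) the target encoding with
the nozzle orifice diameter when diameters are supplied.

## Splitting and cross-validation

APIs are aggregated to profile vectors (means of scaled numeric attributes
plus polymer-type indicators) and k-means-clustered (default 4 clusters; the
attribute subset is configurable). Each cluster contributes
`ceil(0.25 * cluster size)` APIs to the test set, so every population is
represented. Model selection uses leave-one-API-out CV (LOGO): one fold per
training API, score = unweighted mean over folds of the fold RMSE in μm.
Fold encodings are precomputed once per search (they do not depend on the
model spec) — the leakage guarantee is unchanged, the search is ~30× faster.

## Model zoo and ensemble

Families: PLS, ridge, lasso, elastic net, SVR (RBF), kernel ridge (RBF),
random forest, gradient-boosted trees, multilayer perceptron. Defaults are
optimized values for this problem class (PLS 8 components; ridge α=0.78;
lasso α=0.027; SVR C=79.91, ε=0.035; kernel ridge α=γ=0.075; MLP hidden
layers (30, 70)). Multivariate adaptive regression splines are not included
in this build. The MLP is sklearn's (L2 regularization instead of dropout;
deterministic under a fixed seed). The ensemble is the exact arithmetic mean
of member predictions with no ensemble-level fitting; the desk-scale default
membership is PLS + SVR, with the MLP available by configuration.

Hyperparameters are searched by a steady-state evolutionary scheme: uniform
(log-uniform for positive reals) initial population within bounds; each
iteration draws a random tournament, mutates its best member in one
randomly chosen hyperparameter (log-uniform factor in [0.5, 2] for positive
reals, ±1 for integers, clipped to bounds), evaluates the mutant by LOGO-CV
RMSE, and replaces the current worst member. Reference-scale budgets are
population 200 / tournament 40 / 800 iterations; desk-scale defaults are
30 / 8 / 120. CV evaluations are cached by spec hash. Replacement of the
*worst* member is the minimal elitist completion of the
tournament-select-mutate-evaluate loop; the mutation kernel spans the
magnitude range of the default hyperparameters.

## Shapley attribution

Kernel-based Shapley values with the interventional value function: absent
features are replaced by background rows (a fixed 100-row subsample).
Coalitions are sampled proportionally to the Shapley kernel (paired with
their complements); for ≤12 features all coalitions are enumerated and the
result is exact. The coalition regression is solved *subject to* the
additivity constraint (eliminated into the last coefficient), so
`base + Σφ = prediction` holds to solver round-off — the local-accuracy
property is structural, not approximate. Ensemble attributions are member
means, inheriting local accuracy because the ensemble prediction is the
member mean. Global importance ranks features by mean |φ|; the sign trend
is the Spearman correlation between feature value and φ (the numeric
content of a beeswarm plot). Per-instance waterfall tables sort by |φ|; the
local order can legitimately differ from the global ranking.

## Inversion

Given a fixed formulation, dryer scale and target D50 `y`:

1. **Imputation** (search-space location): the problem row joins the
   scale-matched training rows with its process parameters missing. Each
   missing parameter is initialized to the training mean and repeatedly
   re-predicted (randomized order, ridge regression on all other columns
   including D50; BayesianRidge available by option) for 20 passes or until
   the largest change falls below 1e-4 of the parameter's range. Estimates
   are clipped each pass to the scale's training range, except the nozzle
   encoding, clipped to [0.75, 1.25]·y.
2. **Bounds**: ×[0.90, 1.10] around the imputed temperatures, gas flow and
   ratio; ×[0.50, 1.50] for atomization pressure; ×[0.75, 1.25] for the
   nozzle encoding. User-fixed parameters collapse to a point and are never
   imputed; user bounds override.
3. **Penalized global search**: minimize
   `J = |y − ŷ| + 100·H(Q − Q_UCL)(Q/Q_UCL − 1) + 100·H(T² − T²_UCL)(T²/T²_UCL − 1)`
   with the DIRECT space-partitioning sampler (deterministic; budget 200
   evaluations; early stop once J < 0.10·y). H is the Heaviside step with
   H(0) = 0 — immaterial at the limit since the penalty factor is zero
   there; penalties are continuous at the limits and grow linearly beyond.

Success ⇔ |ŷ − y| ≤ 0.10·y and both control statistics within their limits.
The result carries the continuous nozzle encoding plus the nearest training
nozzles as a convenience list; selecting a physical nozzle remains a user
decision.

### Control model

Per-scale PCA on standardized features defines the feasible correlation
structure. The retained component count is the rounded average of three
strategies — eigenvalue-greater-than-mean, Horn's parallel analysis, and a
column-permutation test — never below 1. Limits at α = 99.73%:
`T²_UCL = a(n−1)(n+1)/(n(n−a)) · F⁻¹(α; a, n−a)` (new-observation form) and
the Jackson–Mudholkar closed form for Q_UCL from the moments of the
discarded eigenvalues (zero residual variance ⇒ Q_UCL = +∞ with a warning).
Both limits are Monte-Carlo-calibrated in the test suite.

The control model uses the numeric formulation attributes, process
parameters and nozzle encoding — not the one-hot composition columns and
not the scale indicator (constant within a scale), and not D50 itself.
Measured on held-out genuine operating points, a PCA that includes the
sparse composition indicators flags 27–30% of them as Q violations at
per-scale sample sizes of ~100–400 rows: any legitimate-but-unseen
chemistry combination reads as a correlation break. With the numeric
feature set the false-alarm rate is at the design level. The target D50 is
excluded because it is the quantity being designed, not a settable
parameter.

## Synthetic study conditions

Historical SDD datasets are proprietary, so the package generates its own
with the structure the pipeline assumes. The generative law is

    D50 = base · nozzle_factor · scale_factor · api_effect · solvent_mult
          · ratio^0.40 · pressure^(−0.45) · solids^(1/3) · (1 + 0.012·polymer_loading)

× lognormal noise (default CV 10%), clipped to [8, 104] μm with clipped rows
flagged. The cube-root solids dependence is the shrinking-sphere particle-
formation limit; pressure and ratio exponents encode the experimentally
established directions (higher atomization pressure → smaller particles;
more liquid per unit gas → larger). `solvent_mult` is a fraction-weighted
per-solvent multiplier (acetone/DCM 0.90, methanol/THF 1.05, water 1.30)
standing in for the solvent-viscosity mechanism; without it the solvent
columns would be pure distractor dimensions, which neither matches the
mechanism nor any plausible historical dataset.

Structure choices, made once as study conditions:

- 40 APIs, 8–16 sprays each (~500 rows), 30 nozzles, 25% of campaigns on
  PSD-2. An API's formulation is fixed across its sprays and drawn from the
  standard levels formulators use (integer solids, 5%-step loadings,
  standard solvent splits); continuous per-API values would act as API
  fingerprints that kernel models memorize, an artifact no real dataset
  exhibits because real programs share round-numbered platforms.
- Chemistry pools are weighted toward the field's workhorse systems
  (HPMCAS grades, PVP VA64; acetone/methanol primaries). Water appears only
  as a minor co-solvent: SDD APIs are poorly water-soluble by definition.
- Sprays are organized in campaigns keyed by (nozzle, scale) within an API:
  the solution and solution-to-gas ratio are fixed within a campaign while
  pressure and dryer conditions vary — how pressure scans are actually run.
  Within such a stratum noise-free D50 is strictly decreasing in pressure
  (a tested invariant).
- PSD-2 campaigns draw drying-gas flow from ≥2500 g/min and use nozzles
  with a ×1.2 size step; within a scale, nozzle idiosyncrasy is modest
  (lognormal σ = 0.05): the dominant nozzle effect is the size class tied
  to the flow regime, which is what lets models generalize to unseen
  nozzles — a property real studies of this workflow demonstrate.
- Per-API multipliers (lognormal σ = 0.06) model API-specific morphology
  effects; for held-out APIs they are irreducible error by construction.

What the generator does **not** emulate: droplet-size physics and drying
kinetics, measurement-method (dry-dispersion) artifacts, temporal drift in
historical records, correlated missingness, and operator-chosen (endogenous)
process settings beyond the campaign structure. Passing tests therefore
demonstrate that the pipeline recovers known structure of this kind at this
scale — not that any given real dataset is this learnable.

## Numerical choices and degenerate inputs

- Constant feature columns scale to 0; unseen categories encode to zeros;
  unseen nozzles take the global mean.
- The attribution regression uses `lstsq` on the constrained system;
  a background identical to the instance yields zero contributions with a
  warning.
- Component selection never retains fewer than 1 component; retaining
  `a ≥ min(rows − 1, features)` is an error.
- Imputation clips every pass; DIRECT point-bounds (user-fixed parameters)
  are excluded from the search dimensions.
- All randomness flows from named substreams of a single seed (SHA-256 of
  `seed:stage`, reduced below 2³¹); identical configuration ⇒ byte-identical
  outputs.

## Problem sizes

Defaults throughout are desk-scale: ~500-row datasets, 40-instance
attribution samples with ~90 sampled coalitions over a 100-row background,
50-problem inversion studies with a 200-evaluation search budget, and
30/8/120 evolutionary budgets. All are configurable upward; the
reference-scale budgets quoted above are preserved as options.

## Known limitations

- Held-out-API prediction error is limited by the API count, not the row
  count: formulation attributes are constant within an API, so cross-API
  formulation effects are estimated from only ~30 training APIs at the
  default scale. The PLS+SVR ensemble lands at roughly 0.5–0.6 of the
  held-out D50 standard deviation there (generator Bayes floor ≈ 0.33);
  doubling the API pool brings it clearly below 0.5. Evolved
  hyperparameters do not help at this scale — the grouped-CV criterion
  itself overfits with so few groups.
- Inversion solves a many-to-one problem; different parameter combinations
  yield the same predicted size, and the control-limit penalty selects
  historically plausible ones, not unique ones. Atomization-quality lower
  bounds on pressure are not modeled.
- The evolutionary search at desk-scale budgets can overfit the CV
  criterion for flexible families (its purpose is hyperparameter location,
  not model comparison).
- MARS is unavailable; the MLP substitutes L2 regularization for dropout.
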