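# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `drugcombo`.

## Problem setting

Two cell types (a "cancer-like" line to be inhibited and a "normal-like"
line to be preserved) are exposed to combinations of a small drug panel on
a full factorial concentration grid.  The measured quantity is viability
normalized to the untreated control, so responses live in [0, 1] and the
all-zero combination reads 1 by construction.  Only a small uniform random
subset of the grid is assumed measured; everything downstream operates on
model predictions over the full grid.

The default panels are a 3-drug panel (AG490, U0126,
indirubin-3′-monoxime; 8 levels each, 512 combinations) and a 4-drug panel
adding the PKC inhibitor GF109203X (7 levels each, 2401 combinations), with
log-like level spacings from 0 to 30–300 µM chosen to span minimal to
maximal single-agent effect.  Grid rows are ordered lexicographically with
the last drug's level index varying fastest; this canonical order is the
tie-break for ranking and the indexing base for training designs.

## Response-surface families

All four families consume concentrations unit-scaled by the per-drug
maximum grid level.  Raw µM values span three orders of magnitude; product
regressors on raw values are numerically ill-conditioned, and zero doses
must stay exactly zero (which rules out log scaling).

* **LR_FULL_INTERACTION.**  OLS with intercept on one product term per
  non-empty drug subset (2ⁿ−1 regressors, canonical order: singletons,
  pairs, …, lexicographic within a size).  With n ≤ 4 drugs at 2 levels the
  parameter count equals the grid size and the model interpolates exactly —
  used as an internal oracle in the tests.
* **QUADRATIC_RSF.**  OLS with intercept on linear terms, pairwise products
  and squares (2n + n(n−1)/2 regressors).
* **MLP_1x4.**  y = w₂ᵀ tanh(W₁ᵀx + b₁) + b₂ with 4 hidden units.
* **CASCADE_2x1.**  One tanh unit h = tanh(w₁ᵀx + b₁) and a linear output
  over the concatenation [x, h] (cascade-forward: the output layer sees the
  raw inputs as well).

An intercept is always included in the linear families: the untreated
response is 1, not 0.  Underdetermined linear systems raise an error rather
than silently returning a minimum-norm solution, because downstream subset
comparisons would be corrupted; an explicit `ridge` flag enables a small L2
penalty (intercept unpenalized, λ = 10⁻⁶ by default) when a fit is wanted
anyway.

**Network training.**  Networks minimize the evidence-framework objective
βE_D + αE_W (E_D = half the SSE, E_W = half the squared weight norm, biases
included).  Each outer iteration runs L-BFGS-B on the current (α, β), then
re-estimates the effective number of parameters γ = Σ λᵢ/(λᵢ + α) from the
eigenvalues λᵢ of the Gauss–Newton Hessian βJᵀJ and updates α = γ/2E_W,
β = (N − γ)/2E_D.  Outer iterations stop when the hyperparameters move by
less than 10⁻⁶ (relative) or after 30 rounds; hitting the budget emits a
convergence warning and returns the best model found.  Weights initialize
uniformly at ±1/√fan-in per layer under a seeded generator; 5 restarts are
run by default and the restart with the lowest final training MSE wins,
ties going to the lowest restart index.  Training is deterministic given
the spec's seed.

**Saturation.**  Model outputs are clamped to [0, 1] at prediction time
only, never inside the training loss — saturation is post-processing of the
learned surface, not part of the objective.

## Performance function

A response pair (x_nc, x_cc) is scored by a diagonal Gaussian kernel
centered at the ideal pair μ = (1, 0) — normal cells untouched, cancer
cells dead:

    raw = exp(−(x_nc − 1)²/(2σ²_nc) − x_cc²/(2σ²_cc)),

rescaled affinely as (raw − 0.25)/0.14 × 100 and hard-clamped to [0, 100]
(the affine map alone exceeds both ends, so clamping is the minimal
mechanism delivering the stated range).  The default variance
σ²_nc = 0.4296 is calibrated in closed form so that the total-kill pair
(0, 0) scores 44.48: exp(−1/2σ²) = 0.25 + 0.14·0.4448.  Only the normal
axis is pinned by that anchor; σ²_cc defaults to the same value for
symmetry and is exposed as a parameter.

One structural consequence worth knowing: the affine rescale reaches 100
already at raw = 0.39, i.e. on the disc (x_nc−1)² + x_cc² ≤ 0.81.  A large
fraction of a typical response map therefore ties at the clamped top
score; ranking inside the plateau falls back to the canonical grid order,
and the k-means grouping of scores is the more informative summary there.

## Selection stages

Ranking, k-means clustering (1-D on scores, k-means++ with 10 restarts,
ids relabeled 1..k by ascending center), mixture analysis and conditional
curves/surfaces are pure selections over the score map.  A mixture's
restriction always contains the all-zero row, and the best achievable score
is monotone under mixture inclusion by construction — the nesting property
asserted in the tests is an exact consequence of the definition, which is
why the package checks it as an invariant rather than a statistical
outcome.  Clustering operates on scores; clustering on (x_nc, x_cc) pairs
would also be defensible but mixes the objective back into the grouping,
so it is not the default.

## Interaction inference

Per cell type, the response is regressed on the 15 full-interaction
regressors of the 4-drug basis.  The search is exhaustive: all 2¹⁵ − 1 =
32 767 subsets, each solved via the precomputed augmented Gram matrix
(Cholesky per subset), keeping the minimum-RSS model of every size.
Rank-deficient subsets are skipped.  Exhaustiveness makes RSS non-increasing
in model size and makes the size-15 model identical to full OLS — both are
tested.  The model size is picked by an elbow rule: the smallest s such
that every larger size improves RSS by less than τ (relative), default
τ = 0.01.  The threshold is a judgment call — "no further significant
reduction" is not a sharp criterion — so τ is a configuration knob and the
resulting sizes are data-dependent observations, not targets.

Coefficient signs are reported per term; positive-scaling any drug's
concentration axis leaves scaled regressors, hence subsets and signs,
unchanged.  Two cell types' selected term sets are partitioned into
common / A-only / B-only by membership.

## Synthetic-data generator

The generator emulates the statistical structure of a two-cell-type
factorial viability screen:

* **Single drugs:** Hill survival v(c) = 1 − i_max·cʰ/(cʰ + EC50ʰ).
* **Baseline combination rule:** Bliss independence — survival is the
  product of single-drug survivals.
* **Interactions:** planted terms γ_T·Π_{i∈T} s_i added to the Bliss
  product, with s_i = 1 − v_i the fractional inhibition; γ < 0 deepens
  killing, γ > 0 rescues.  Acting on inhibition products (not raw
  concentrations) keeps γ scale-free and leaves zero-dose rows exactly at
  1, preserving the untreated normalization.
* **Noise:** additive Gaussian, clamped to [0, 1], default σ = 0.05 — a
  typical plate-to-plate scatter for normalized luminescence; no
  quantitative error model is available for the assay this emulates, so σ
  is swept in tests rather than asserted.

**Reference scenario.**  `default_two_celltype_scenario()` fixes two truths
on the 4-drug panel.  The cancer-like cell is sensitive to AG490, I-3-M and
GF109203X (i_max ≈ 0.5–0.55, EC50 mid-grid, h = 1.2) and nearly resistant
to U0126; the normal-like cell responds gently to AG490, U0126 and I-3-M
(i_max ≈ 0.3–0.35, shallower EC50s, h = 1.0) and barely to GF109203X.
Planted interactions: a shared AG490×I-3-M antagonism (+0.35 cancer, +0.25
normal), a cancer-only AG490×GF109203X synergy (−0.30) and a normal-only
U0126×I-3-M antagonism (+0.25).

Two construction choices deserve explanation.  First, expanding the Bliss
product shows every pair of drugs a cell type responds to contributes its
own +s_i·s_j cross-term, so single-agent sensitivities were concentrated on
the drugs each cell type's planted interactions involve — otherwise
baseline cross-terms would appear in both cell types' selected sets and the
common/private partition would be unrecoverable by any regression.  Second,
the shared term is antagonistic so that it reinforces the baseline
cross-term in both cell types rather than cancelling against it (a planted
synergy of −0.25 sits under a baseline of +1 on the same product and can
null the net coefficient).  Selected models on this scenario also contain a
few additional baseline-induced terms (for example I-3-M×GF109203X in the
cancer-like cell); this is expected and correct — they are genuine
curvature of the Bliss surface, and the recovery tests assert the placement
of the planted terms, not set equality.

A documented combination (AG490 30, U0126 0.3, I-3-M 30, GF109203X 10 µM)
yields truth responses ≈ 0.40 (cancer-like) versus ≈ 0.77 (normal-like) and
serves as the scenario's selectivity anchor.

**What the generator does not emulate:** plate/edge effects and systematic
batch shifts, replicate-correlated noise, heteroscedasticity near 0 and 1,
mechanistic pathway dynamics, and time-course behavior (a single endpoint
is modeled).  Passing tests therefore demonstrate that the algorithms
recover structure they are designed for under idealized independence
assumptions — not that any particular laboratory screen satisfies those
assumptions.

## Problem sizes and determinism

The default experiments are sized for a laptop-class single CPU: model
recovery uses 80/512-point designs on the 3-drug grid, interaction
inference uses the full 2401-row 4-drug grid or a 148-point design, and the
exhaustive 32 767-model search runs in about a second per cell type via the
Gram-matrix formulation.  Every stochastic step (design sampling, noise,
network initialization, clustering) takes an explicit integer seed, and the
pipeline writes a manifest of seeds so any stage can be re-run in
isolation; two runs of the same configuration are byte-identical.

## Known limitations

* The Gaussian performance kernel's cancer-axis variance is a convention
  (see above); scores other than the calibrated anchors depend on it.
* The elbow threshold τ trades parsimony against sensitivity; very low
  noise inflates selected model sizes because tiny baseline terms become
  statistically resolvable.
* Best-subset enumeration is exponential in the regressor count; it is
  comfortable at p = 15 but a different strategy (leaps-and-bounds or
  regularization paths) would be needed far beyond that.
* Network training optimizes a non-convex objective; restarts make the
  outcome reproducible, not globally optimal.
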