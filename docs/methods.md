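# Methods

## Problem setting

The package predicts three DXA-measured body-composition variables —
appendicular lean mass (ALM, kg), body-fat percentage (BFP, %) and bone
mineral density (BMD, g/cm²) — from 44 digital anthropometric biomarkers, in
a transductive setting: all participants (labeled and unlabeled) are known at
training time, and the question is how prediction accuracy degrades as the
labeled fraction shrinks. Analyses are run per stratum (male, female,
combined) because all three targets are strongly sex-dependent.

## Graph model

Participants are vertices. Biomarkers are z-scored over **all** vertices
(population-SD convention, divide by n) before graph construction — the graph
is a property of the whole cohort, not of a training fold — and each vertex
is joined to its k nearest neighbors in Euclidean distance, with the edge set
symmetrized by union. Edge weights are Gaussian,
`w_ij = exp(-(d_ij/ε)²) ∈ (0, 1]`, with one global scale ε. ε has no
canonical value; the default rule sets it to the mean k-th-neighbor distance,
which adapts to data density and keeps weights far from underflow. A fixed ε
can be supplied instead. Distance ties at the k-th neighbor break toward the
lowest vertex index (stable sort), making the edge set deterministic.
Self-loops are excluded; neighborhoods are open.

Two graph variants are evaluated: `plap1` uses all 44 biomarkers; `plap2`
uses the 10 biomarkers most |Pearson|-correlated with the target. For
`plap2` the default ranks features on the training fold only (leakage-free);
a `global` mode ranks once on all rows, reproducing a fixed whole-dataset
top-10 list.

## The p-Laplacian Dirichlet problem

Training vertices Γ are pinned to their measured values g. Every unlabeled
vertex carries the value function of a tug-of-war game with noise,
characterized by the dynamic programming principle (DPP)

    u(i) = (α/d_i) Σ_{j∈N_i} w_ij u(j) + (1−α)/2 (min_{N_i} u + max_{N_i} u)

with α = 1/(p−1) for p ∈ [2, ∞]; p = ∞ is admitted exactly as α = 0 rather
than via a large-p approximation. Other parameterizations of the
game-theoretic p-Laplacian exist in the literature (e.g. splitting the α
weight between the mean and midrange differently); this package follows the
α = 1/(p−1) convention exclusively.

Every DPP update is a convex combination of neighbor values, so the operator
is monotone and satisfies a maximum principle: solutions stay within
[min g, max g] on each component, provided every connected component holds at
least one labeled vertex — a precondition validated explicitly
(`ensure_connected`), with strict single-component mode available.

### Solver

Fixed-point iteration with Gauss–Seidel sweeps in vertex order (deterministic
and roughly twice as fast as Jacobi in contraction per sweep); the inner
sweep is JIT-compiled over the CSR arrays. Unlabeled vertices start at the
label mean (any start in the label range preserves the maximum principle
throughout). Convergence is declared when the sup-norm sweep update falls
below `0.1 · tol · range(g)` with `tol = 1e-6` and a budget of 1e5 sweeps;
the factor 10 between the update residual and the target accuracy covers the
gap between the Gauss–Seidel update size and the true fixed-point error under
linear convergence (calibrated against the direct harmonic solve: solutions
agree with the p = 2 linear system to ~1e-6 sup-norm on small graphs).
Non-convergence is reported in the solution diagnostics, never raised.
When sweeping a p grid the solver warm-starts from the previous p's solution.
The operator residual `DPP(u) − u` is exposed via `dpp_update` for
diagnostics.

At p = 2 the problem is linear and a direct sparse solve
(`harmonic_oracle`) provides an independent cross-check; the test suite
verifies agreement on randomized graphs, plus monotone comparison, affine
equivariance, and linear interpolation on chain graphs for both p = 2 and
p = ∞.

Note on large p: the *solution* moves O(Δα) between finite p values (e.g.
~1e-3 sup-norm between p = 100 and p = 200 on unit-scale labels); what
converges as p → ∞ is the sequence of solutions toward the α = 0 limit, and
with it the evaluation RMSE. The asymptotic sweep therefore reports
successive RMSE differences, which shrink by orders of magnitude between
(p = 3, 10) and (p = 100, 200).

## Evaluation protocol

Accuracy is `RMSE% = 100 · sqrt(mean((ŷ−y)²)) / sqrt(mean(y²))`, computed
per test fold and then averaged over folds and runs (the fold is the unit;
folds are not pooled). Cross-validation is repeated R = 10 times with
re-randomized folds; the solver itself is deterministic, so repeats vary only
the partition. Two modes:

- **standard**: each fold is the test set once; training fraction (K−1)/K
  (K = 5 → 80/20);
- **modified**: each fold is the *training* set once and the other K−1 folds
  are tested; training fraction 1/K, so K ∈ {2, 3, 4, 5, 10, 20} yields
  training percentages {50, 33.3, 25, 20, 10, 5}. The training fold rotates
  over all K positions per run so all data is used symmetrically.

Hyperparameter selection is the argmin of mean RMSE% over the (p, k) grid
(default p = 2…10 step 0.5 plus ∞; k = 5…60 step 5), ties broken toward
smaller p then smaller k. Graphs are rebuilt per (feature set, k) and shared
across p values, runs and folds; only the pinned label set changes.

## Supervised baselines

The supervised layer exists to compare label efficiency under an identical
protocol, not to contribute estimator math, so estimators delegate to
scikit-learn and XGBoost: linear/ridge/lasso/Bayesian regression, polynomial
regression (degree 2 with an L2 penalty), ε-SVR, least-squares SVR (realized
as RBF kernel ridge regression, the same squared-loss kernel problem, with
C ↦ 1/(2α)), random forest, gradient boosting, and an MLP (ReLU, Adam,
L2 penalty; hidden sizes default to (64, 32) as a convention). Scaling is
fit on the training fold only and applied to the test fold — the
transductive whole-cohort normalization is deliberate and correct only for
the graph model, where unlabeled features are legitimately available.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at the
study's scale: two strata (245 males, 270 females), 44 biomarkers, three
targets. Per sex, the joint law is a Gaussian copula:

- **Marginals.** Six variables per sex carry study-calibrated means/SDs
  (ALM, BFP, BMD, Age, Height, Weight — e.g. male ALM 21.88 ± 7.95 kg,
  female BFP 34.71 ± 7.37%); the remaining biomarkers carry plausible
  anthropometric conventions for a mixed adolescent/adult cohort, shipped as
  a versioned default table (female values scale the male conventions by
  0.93, volumes by 0.84). ALM and Age are right-skewed and use a
  moment-matched lognormal (mean > median, as observed); everything else is
  normal. BFP is clipped to (0, 100). Marginal transforms preserve the
  prescribed mean and SD exactly in expectation.
- **Correlation.** The latent matrix starts from the calibrated top-10
  biomarker–target correlations per sex and target, left/right bilateral
  pairs at ρ = 0.95, and a background of 0.3. Unspecified biomarker pairs
  that share a calibrated target are filled single-factor-consistently
  (ρ_ij = max over targets of ρ_it·ρ_jt), and target–target entries likewise
  from shared biomarkers — without this, ten biomarkers each correlated ~0.9
  with ALM but only 0.3 with each other form a badly indefinite matrix, and
  a plain nearest-PSD projection would drag the calibrated entries by up to
  0.35. The repair is alternating projections onto the PSD cone that hold
  the calibrated and bilateral entries fixed, finished with a tiny
  eigenvalue clip: the result is PSD (min eigenvalue ≥ −1e−8) with
  calibrated entries preserved to ~1e−6.
- **Sampling.** Latent Gaussians via an eigendecomposition factor, then
  marginal transforms. The lognormal transform attenuates Pearson
  correlations slightly (≈3% at ρ ≈ 0.96 for the male ALM skew), which stays
  within the generator's ±0.05 recovery tolerance and is accepted rather
  than pre-compensated.
- **Missingness fixture.** `inject_missingness` blanks 1–3 biomarker cells
  in exactly n_incomplete uniformly chosen rows (MCAR) — enough to exercise
  listwise deletion (847 → 332 incomplete → 515 complete); no imputation is
  implemented, matching the cleaning rule. The real study's missingness
  mechanism is uncharacterized; MCAR is the neutral choice.

What the generator does **not** emulate: scanner-specific measurement error,
multi-site effects, the real cohort's full 44×44 correlation fine structure
(only the calibrated sub-blocks are matched), race/ethnicity structure, and
any nonlinear biomarker–target relationships beyond what the copula induces.
Passing tests therefore demonstrate protocol and solver correctness and
qualitative label-efficiency behavior, not clinical accuracy on real
cohorts; real-data RMSE levels are expected to differ.

## Combined-cohort identities

The combined stratum is the concatenation of the sex strata, so combined
means are size-weighted per-sex means: ALM (245·21.88 + 270·15.77)/515 ≈
18.68 kg, BMD ≈ 1.033 g/cm² (prints as 1.03 at two decimals). Combined-level
correlations are allowed to emerge from concatenation rather than being
enforced.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run at the study's own scale (n = 515 per
cohort; 10 cohorts for moment recovery; 10 CV runs) with small (p, k) grids
— p ∈ {2, 3} with k = 10 for the label-efficiency trend, and
k ∈ {10, 30, 50} × p ∈ {3, 10, 100, 200} at 20% training for the asymptotic
sweep — chosen as the smallest designs that exhibit the protocol's
qualitative behavior; the full default grids remain available through the
API and CLI.

## Known limitations

- ε and the generator's uncalibrated marginals are conventions; results on
  synthetic data shift with them (means/SDs shift marginally, graph topology
  with ε).
- The DPP iteration's convergence rate degrades as α → 0 on weakly connected
  graphs; the 1e5-sweep budget has been ample in practice, but
  non-convergence is possible and is reported in diagnostics.
- Pearson-based feature ranking captures linear association only.
- The MLP baseline does not implement dropout; regularization is L2 only.
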