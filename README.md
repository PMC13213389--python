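# bodycomp

Graph-based semi-supervised prediction of body-composition variables —
appendicular lean mass (ALM, kg), body-fat percentage (BFP, %) and bone
mineral density (BMD, g/cm²) — from digital anthropometric biomarkers
(circumferences, lengths, surface areas, volumes extracted from 3D body
scans).

These three variables are normally measured with DXA scans, which are costly
and slow, so labeled data is scarce. `bodycomp` implements and evaluates a
label-efficient alternative: treat every participant (labeled or not) as a
vertex of a k-nearest-neighbor similarity graph over z-scored biomarkers,
with Gaussian edge weights

```
w_ij = exp(-(‖x_i - x_j‖ / ε)²),
```

pin the known target values g on the training vertices Γ, and solve the
game-theoretic p-Laplacian Dirichlet problem for the remaining vertices via
its tug-of-war dynamic programming principle

```
u(i) = (α / d_i) Σ_{j∈N_i} w_ij u(j) + (1-α)/2 · (min_{N_i} u + max_{N_i} u),
α = 1/(p-1),  d_i = Σ_j w_ij,
```

with p ∈ [2, ∞]: p = 2 (α = 1) is the harmonic / random-walk regression,
p = ∞ (α = 0) the pure tug-of-war (infinity-harmonic) limit. Accuracy is
scored as RMSE normalized by the RMS of the truth, in percent, under repeated
K-fold cross-validation — including a *modified* mode that trains on one fold
and tests on the other K−1, giving training fractions 1/K for
label-efficiency curves. A thin supervised layer (linear/ridge/lasso/
Bayesian/polynomial regression, SVR, least-squares SVR, random forest,
gradient boosting, MLP) runs under the same protocol for comparison.

Because the motivating study's cohort is not publicly deposited, the package
ships a first-class synthetic cohort generator: a Gaussian copula per sex
(245 males + 270 females by default) calibrated to the study's published
marginal moments and top-10 biomarker–target correlations, with bilateral
left/right correlation structure and an optional missing-data fixture
(847 enrolled → 332 incomplete → 515 complete cases).

Audience: biostatisticians and ML researchers studying label-efficient
regression on clinical tabular data, and anyone needing a reproducible
testbed for graph-based semi-supervised regression.

## Worked example

```python
from bodycomp import (default_cohort_spec, generate_cohort, CVPlan,
                      ExperimentConfig, run_plaplace_experiment, argmin_view)

cohort = generate_cohort(default_cohort_spec(), seed=1)   # 515 participants

for K in (2, 5, 10, 20):                    # training fractions 50..5 %
    results = run_plaplace_experiment(cohort, ExperimentConfig(
        target="ALM", dataset="combined", variant="plap1",
        p_grid=(2.0, 3.0, 5.0), k_grid=(10, 30),
        cv=CVPlan(K=K, mode="modified", repeats=10, seed=0)))
    best = argmin_view(results).iloc[0]
    print(f"Training% {100/K:5.1f}  best p={best.p:.0f} k={best.k:.0f}"
          f"  RMSE% {best.rmse_percent:.2f}")
```

Output:

```
Training%  50.0  best p=3 k=10  RMSE% 13.75
Training%  20.0  best p=3 k=10  RMSE% 16.74
Training%  10.0  best p=3 k=10  RMSE% 19.53
Training%   5.0  best p=3 k=10  RMSE% 22.62
```

Each line is the best mean test RMSE% (over 10 runs × K folds) across the
(p, k) grid for ALM on the combined synthetic cohort: the error grows
monotonically as the labeled fraction shrinks from 50% to 5%, and a
moderately nonlinear p (here p = 3) with a small neighborhood (k = 10) is
preferred. The same harness exposes the top-10-feature graph variant
(`variant="plap2"`), the supervised baselines
(`run_baseline_experiment`), and large-p asymptotic sweeps
(`asymptotic_sweep`).

The `bodycomp` console script wraps the same functions: `bodycomp simulate`,
`bodycomp run-plaplace`, `bodycomp run-baselines`, `bodycomp sweep-p`,
`bodycomp report`.

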