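"""Label-efficiency evaluation protocol for the graph regression models.

Implements the study protocol: RMSE expressed as a percentage of the RMS of
the true values, repeated K-fold cross-validation in two modes (standard:
train on K-1 folds; modified: train on ONE fold and test on the other K-1,
giving training fractions 1/K for label-efficiency curves), hyperparameter
sweeps over (p, k), the two graph variants (all 44 biomarkers vs the top-10
most target-correlated), and large-p asymptotic sweeps.

Results are tidy :class:`pandas.DataFrame` tables with one row per
(target, dataset, variant, p, k, training_percent, run, fold) cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import build_knn_graph
from .plaplace import LabelSet, PLaplaceConfig, solve_plaplace
from .preprocessing import pearson_rank, stratify_by_sex, top_m, zscore_apply, zscore_fit
from .synthetic_cohort import Cohort

__all__ = [
    "CVPlan",
    "ExperimentConfig",
    "rmse_percent",
    "make_splits",
    "run_plaplace_experiment",
    "asymptotic_sweep",
    "aggregate",
    "argmin_view",
]

RESULT_COLUMNS = [
    "target",
    "dataset",
    "variant",
    "p",
    "k",
    "training_percent",
    "run",
    "fold",
    "rmse_percent",
]


def rmse_percent(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """RMSE normalized by the RMS of the true values, in percent:
    ``100 * sqrt(mean((pred - true)^2)) / sqrt(mean(true^2))``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    denom = np.sqrt(np.mean(y_true**2))
    if denom == 0:
        raise ZeroDivisionError("RMSE%% undefined: true values are all zero")
    return float(100.0 * np.sqrt(np.mean((y_pred - y_true) ** 2)) / denom)


@dataclass
class CVPlan:
    """Cross-validation plan.

    mode="standard": each fold is the test set once (training fraction
    (K-1)/K). mode="modified": each fold is the TRAINING set once and the
    remaining K-1 folds are tested (training fraction 1/K); the training fold
    rotates so all data is used symmetrically.
    """

    K: int = 5
    mode: str = "standard"
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.mode not in ("standard", "modified"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def training_fraction(self) -> float:
        return (self.K - 1) / self.K if self.mode == "standard" else 1.0 / self.K

    @property
    def training_percent(self) -> float:
        return 100.0 * self.training_fraction


def make_splits(n: int, plan: CVPlan, run: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random K-fold partition for one run, seeded by (plan.seed, run).

    Returns K (train, test) index pairs; folds are disjoint and exhaustive,
    near-equal in size.
    """
    if plan.K > n:
        raise ValueError(f"K={plan.K} exceeds n={n}")
    rng = np.random.default_rng([plan.seed, run])
    perm = rng.permutation(n)
    folds = np.array_split(perm, plan.K)
    splits = []
    for f in range(plan.K):
        fold = folds[f]
        rest = np.concatenate([folds[g] for g in range(plan.K) if g != f])
        if plan.mode == "standard":
            splits.append((np.sort(rest), np.sort(fold)))
        else:
            splits.append((np.sort(fold), np.sort(rest)))
    return splits


def _default_p_grid() -> tuple[float, ...]:
    return tuple(np.arange(2.0, 10.5, 0.5)) + (math.inf,)


def _default_k_grid() -> tuple[int, ...]:
    return tuple(range(5, 65, 5))


@dataclass
class ExperimentConfig:
    """One p-Laplacian experiment: target, stratum, variant and grids.

    variant="plap1" builds the graph from all 44 biomarkers; "plap2" from the
    10 biomarkers most correlated with the target. feature_mode controls how
    plap2 picks them: "fold" ranks on the training fold only (leakage-free
    default), "global" ranks once on all rows (reproducing a fixed
    whole-dataset list).
    """

    target: str = "ALM"
    dataset: str = "combined"
    variant: str = "plap1"
    p_grid: tuple[float, ...] = field(default_factory=_default_p_grid)
    k_grid: tuple[int, ...] = field(default_factory=_default_k_grid)
    cv: CVPlan = field(default_factory=CVPlan)
    feature_mode: str = "fold"
    n_features: int = 10
    solver_tol: float = 1e-6
    solver_max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.target not in ("ALM", "BFP", "BMD"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.dataset not in ("male", "female", "combined"):
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.variant not in ("plap1", "plap2"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.p_grid or not self.k_grid:
            raise ValueError("p_grid and k_grid must be nonempty")
        if any(p < 2 for p in self.p_grid):
            raise ValueError("all p values must be >= 2")
        if self.feature_mode not in ("fold", "global"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


def _select_stratum(cohort: Cohort, dataset: str) -> Cohort:
    if "sex" in cohort.frame.columns:
        return stratify_by_sex(cohort)[dataset]
    return cohort


def run_plaplace_experiment(cohort: Cohort, config: ExperimentConfig) -> pd.DataFrame:
    """Full (p, k, run, fold) sweep of the graph regression.

    For each cell: z-score all vertices (transductive normalization), select
    the variant's feature set, build the k-NN graph over all vertices, pin
    the training fold's target values, solve the Dirichlet problem, and score
    RMSE% on the test vertices only. Deterministic given config.cv.seed.
    """
    data = _select_stratum(cohort, config.dataset)
    names = list(data.biomarker_names)
    X_raw = data.X
    y = data.y(config.target)
    n = data.n
    plan = config.cv

    p_grid = tuple(sorted(config.p_grid))
    graph_cache: dict[tuple, object] = {}
    rows = []
    for run in range(plan.repeats):
        splits = make_splits(n, plan, run)
        for fold, (train, test) in enumerate(splits):
            if config.variant == "plap1":
                feats = names
            elif config.feature_mode == "global":
                feats = top_m(pearson_rank(X_raw, y, names), config.n_features)
            else:
                ranked = pearson_rank(X_raw[train], y[train], names)
                feats = top_m(ranked, config.n_features)
            cols = [names.index(f) for f in feats]
            for k in config.k_grid:
                key = (k, tuple(cols))
                if key not in graph_cache:
                    Xf = X_raw[:, cols]
                    Z = zscore_apply(zscore_fit(Xf), Xf)
                    graph_cache[key] = build_knn_graph(Z, k=k)
                graph = graph_cache[key]
                labels = LabelSet(train, y[train])
                u_prev = None
                for p in p_grid:
                    sol = solve_plaplace(
                        graph,
                        labels,
                        PLaplaceConfig(
                            p=p,
                            tol=config.solver_tol,
                            max_iter=config.solver_max_iter,
                            u0=u_prev,
                        ),
                    )
                    u_prev = sol.u
                    rows.append(
                        {
                            "target": config.target,
                            "dataset": config.dataset,
                            "variant": config.variant,
                            "p": p,
                            "k": k,
                            "training_percent": plan.training_percent,
                            "run": run,
                            "fold": fold,
                            "rmse_percent": rmse_percent(y[test], sol.u[test]),
                        }
                    )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def asymptotic_sweep(
    cohort: Cohort,
    k_values=(10, 30, 50),
    p_values=(3.0, 10.0, 100.0, 200.0),
    training_percent: float = 20.0,
    target: str = "ALM",
    dataset: str = "combined",
    variant: str = "plap1",
    repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """RMSE% per (k, p) at a fixed training fraction, for large-p behavior.

    Uses modified K-fold CV with K = 100 / training_percent. The returned
    table carries a ``delta`` column with the successive RMSE% difference
    along increasing p within each k, documenting convergence as p grows.
    """
    p_values = tuple(p_values)
    if any(b <= a for a, b in zip(p_values, p_values[1:])):
        raise ValueError("p_values must be strictly increasing")
    K = int(round(100.0 / training_percent))
    cells = run_plaplace_experiment(
        cohort,
        ExperimentConfig(
            target=target,
            dataset=dataset,
            variant=variant,
            p_grid=p_values,
            k_grid=tuple(k_values),
            cv=CVPlan(K=K, mode="modified", repeats=repeats, seed=seed),
        ),
    )
    agg = (
        cells.groupby(["k", "p"], as_index=False)["rmse_percent"]
        .mean()
        .sort_values(["k", "p"])
        .reset_index(drop=True)
    )
    agg["delta"] = agg.groupby("k")["rmse_percent"].diff()
    agg.insert(0, "target", target)
    agg.insert(1, "dataset", dataset)
    agg.insert(2, "variant", variant)
    agg["training_percent"] = training_percent
    return agg


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean RMSE% over runs and folds for each experimental cell."""
    keys = ["target", "dataset", "variant", "p", "k", "training_percent"]
    return results.groupby(keys, as_index=False)["rmse_percent"].mean()


def argmin_view(results: pd.DataFrame) -> pd.DataFrame:
    """Best (p, k) per (target, dataset, variant, training_percent).

    Ties break toward smaller p, then smaller k.
    """
    agg = aggregate(results)
    agg = agg.sort_values(["rmse_percent", "p", "k"], kind="stable")
    keys = ["target", "dataset", "variant", "training_percent"]
    return agg.groupby(keys, as_index=False).first()
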