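"""Cleaning, sex stratification, z-scoring and correlation-based feature ranking.

These are the steps the study protocol applies between the raw participant
table and any model: listwise deletion of incomplete records (no imputation),
splitting into male / female / combined strata, standard-scaling of features,
and ranking biomarkers by Pearson correlation with the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import TARGET_NAMES, Cohort

__all__ = [
    "DegenerateInputError",
    "ConstantFeatureError",
    "ScalerParams",
    "RankedFeatures",
    "clean_cohort",
    "stratify_by_sex",
    "zscore_fit",
    "zscore_apply",
    "pearson_rank",
    "top_m",
]


class DegenerateInputError(ValueError):
    """All rows removed, or an otherwise empty/unusable input."""


class ConstantFeatureError(ValueError):
    """A zero-variance feature cannot be z-scored or correlated."""


def clean_cohort(cohort: Cohort, excluded_columns: Sequence[str] = ()) -> Cohort:
    """Listwise deletion plus column exclusion.

    Drops every row with at least one missing biomarker or target cell, then
    drops ``excluded_columns`` (absent names are a no-op). Row order is
    preserved.
    """
    frame = cohort.frame
    check_cols = [*cohort.biomarker_names, *TARGET_NAMES]
    complete = frame[check_cols].notna().all(axis=1)
    out = frame.loc[complete].drop(
        columns=[c for c in excluded_columns if c in frame.columns]
    )
    if out.empty:
        raise DegenerateInputError("no complete rows remain after cleaning")
    return Cohort(out.reset_index(drop=True), cohort.biomarker_names)


def stratify_by_sex(cohort: Cohort) -> dict[str, Cohort]:
    """Split into {male, female, combined}; the sex column is removed from
    each output stratum (sex is encoded by the stratum itself)."""
    sex = cohort.frame["sex"]
    unknown = set(sex.unique()) - {"male", "female"}
    if unknown:
        raise ValueError(f"unknown sex categories: {sorted(unknown)}")
    out = {}
    for name in ("male", "female"):
        sub = cohort.frame.loc[sex == name].drop(columns=["sex"]).reset_index(drop=True)
        out[name] = Cohort(sub, cohort.biomarker_names)
    out["combined"] = Cohort(
        cohort.frame.drop(columns=["sex"]).reset_index(drop=True), cohort.biomarker_names
    )
    return out


@dataclass
class ScalerParams:
    """Per-feature location/scale learned from a reference (training) set.

    Uses the population SD convention (divide by n), matching the standard
    scaler used throughout the protocol.
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)


def zscore_fit(X: np.ndarray) -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise DegenerateInputError("cannot fit a scaler on an empty set")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0)
        raise ConstantFeatureError(f"zero-variance feature(s) at column(s) {bad.tolist()}")
    return ScalerParams(mean, sd)


def zscore_apply(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    out = (X - params.mean) / params.sd
    return out[:, 0] if squeeze else out


#: Ordered (feature name, Pearson r), strongest |r| first.
RankedFeatures = list[tuple[str, float]]


def pearson_rank(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> RankedFeatures:
    """Rank features by |Pearson r| with the target, descending.

    Ties and equal |r| keep the original column order (stable sort). The
    sample (n-1) convention is used, as in standard correlation estimators;
    r is invariant to the convention anyway.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise DegenerateInputError("need >= 2 rows to correlate")
    if np.std(y) == 0:
        raise ConstantFeatureError("target is constant; correlation undefined")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    if np.any(sx == 0):
        bad = np.flatnonzero(sx == 0)
        raise ConstantFeatureError(f"constant feature(s) at column(s) {bad.tolist()}")
    r = (Xc * yc[:, None]).sum(axis=0) / (sx * np.sqrt((yc**2).sum()))
    order = np.argsort(-np.abs(r), kind="stable")
    return [(feature_names[j], float(r[j])) for j in order]


def top_m(ranked: RankedFeatures, m: int = 10) -> list[str]:
    if m > len(ranked):
        raise ValueError(f"requested top {m} of only {len(ranked)} features")
    return [name for name, _ in ranked[:m]]


def ranked_to_csv(ranked: RankedFeatures, path_or_buf) -> None:
    pd.DataFrame(ranked, columns=["feature", "r"]).to_csv(path_or_buf, index=False)
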