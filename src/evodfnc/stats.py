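"""Covariate-adjusted group and symptom effect models.

Subject-level dynamic-connectivity features (mean representational
importance per motif, meta-state occupancy rates, snapshot-state occupancy,
exemplar-membership fractions) are regressed per feature:

* group model: OLS of the feature on gender, age, mean frame displacement
  and diagnosis; the diagnosis coefficient's two-sided t test is reported,
  with multiple-comparison correction across features.
* symptom model (patients only): OLS on the six positive-symptom scores
  entered jointly plus age, gender and mean frame displacement, so each
  symptom's effect is adjusted for the others; correction runs across
  features x symptoms.

Benjamini–Hochberg FDR is the default correction; Bonferroni is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, InvalidParameterError, SingularDesignError
from .synthgen import SYMPTOM_COLUMNS

__all__ = [
    "fit_group_model",
    "fit_symptom_model",
    "correct_pvalues",
    "GROUP_COVARIATES",
]

GROUP_COVARIATES = ["gender", "age", "meanFD"]


def correct_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-comparison correction: BH step-up FDR or Bonferroni.

    Returns adjusted q-values, monotone in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise InvalidParameterError(f"unknown correction method {method!r}")


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending columns: those whose removal restores full rank
        base_rank = np.linalg.matrix_rank(arr)
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == base_rank:
                bad.append(col)
        raise SingularDesignError(bad or list(X.columns))


def _feature_frame(features, prefix: str = "f") -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    return pd.DataFrame(arr, columns=[f"{prefix}{j + 1}" for j in range(arr.shape[1])])


def _ols_rows(y: np.ndarray, X: pd.DataFrame, predictors: list[str], feature: str) -> list[dict]:
    n = len(y)
    if np.ptp(y) == 0.0:
        # zero-variance response convention: no effect, p = 1
        return [
            {"feature": feature, "predictor": pred, "coef": 0.0, "t": 0.0, "p": 1.0, "n": n}
            for pred in predictors
        ]
    res = sm.OLS(y, X).fit()
    return [
        {
            "feature": feature,
            "predictor": pred,
            "coef": float(res.params[pred]),
            "t": float(res.tvalues[pred]),
            "p": float(res.pvalues[pred]),
            "n": n,
        }
        for pred in predictors
    ]


def fit_group_model(
    features,
    manifest: pd.DataFrame,
    correction: str = "bh",
) -> pd.DataFrame:
    """Per-feature OLS of feature ~ gender + age + meanFD + diagnosis.

    ``features`` is a subjects x F matrix or DataFrame row-aligned with
    ``manifest``.  Returns an effect table with one row per feature carrying
    the diagnosis coefficient, its two-sided t test, and q-values corrected
    across the F features.
    """
    F = _feature_frame(features)
    if len(F) != len(manifest):
        raise InvalidInputError("features and manifest must have equal row counts")
    cols = GROUP_COVARIATES + ["diagnosis"]
    missing = [c for c in cols if c not in manifest.columns]
    if missing:
        raise InvalidInputError(f"manifest missing columns: {missing}")
    if manifest[cols].isna().any().any():
        raise InvalidInputError("missing covariate values in manifest")
    X = sm.add_constant(manifest[cols].astype(float).reset_index(drop=True))
    if len(X) <= X.shape[1]:
        raise InvalidInputError(
            f"need more than {X.shape[1]} subjects for {X.shape[1] - 1} predictors"
        )
    _check_design(X)
    rows = []
    for col in F.columns:
        rows.extend(_ols_rows(F[col].to_numpy(dtype=float), X, ["diagnosis"], str(col)))
    table = pd.DataFrame(rows)
    table["q"] = correct_pvalues(table["p"].to_numpy(), correction)
    return table


def fit_symptom_model(
    features,
    manifest: pd.DataFrame,
    correction: str = "bh",
) -> pd.DataFrame:
    """Per-feature OLS on the six positive symptoms jointly, patients only.

    Design: intercept + six symptom scores + age + gender + meanFD.  One row
    per (feature, symptom); q-values corrected across features x symptoms.
    """
    F = _feature_frame(features)
    if len(F) != len(manifest):
        raise InvalidInputError("features and manifest must have equal row counts")
    patients = manifest["diagnosis"] == 1
    man = manifest.loc[patients].reset_index(drop=True)
    Fp = F.loc[patients.to_numpy()].reset_index(drop=True)
    missing = [c for c in SYMPTOM_COLUMNS if c not in man.columns]
    if missing:
        raise InvalidInputError(f"manifest missing symptom columns: {missing}")
    if man[SYMPTOM_COLUMNS].isna().any().any():
        raise InvalidInputError("patients with missing symptom scores")
    cols = SYMPTOM_COLUMNS + ["age", "gender", "meanFD"]
    X = sm.add_constant(man[cols].astype(float))
    if len(X) <= X.shape[1]:
        raise InvalidInputError(
            f"only {len(X)} patients for {X.shape[1]} design columns"
        )
    _check_design(X)
    rows = []
    for col in Fp.columns:
        rows.extend(_ols_rows(Fp[col].to_numpy(dtype=float), X, SYMPTOM_COLUMNS, str(col)))
    table = pd.DataFrame(rows)
    table["q"] = correct_pvalues(table["p"].to_numpy(), correction)
    return table
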