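"""Least-squares regression suite with inference and Holm correction.

Three models probe how the lateral angle develops:

* model A — angle on age: the raw developmental trend;
* model B — the simple angle-breadth regression, reported in both
  directions (R-squared is direction-invariant);
* model C — angle on age and breadth jointly: the covariate adjustment
  that asks whether age carries information beyond cranial breadth.

Coefficients are raw (unstandardised) slopes in natural units
(degrees/year, degrees/mm); standardised betas are available via
``standardized=True``.  Missing values are handled by complete-case
deletion.  Fits are delegated to statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_data import CohortTable

__all__ = ["CoefEstimate", "OlsFit", "ModelSuite", "fit_ols",
           "model_suite", "holm_adjust", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Design matrix is rank-deficient (collinear predictors)."""


@dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    se: float
    t: float
    p: float
    std_estimate: float | None = None  # standardized beta, if requested


@dataclass(frozen=True)
class OlsFit:
    """Ordinary least-squares fit with t-based inference.

    ``coefficients`` maps term name (``"const"`` plus each predictor) to
    its :class:`CoefEstimate`; p-values are two-sided from the t
    distribution with n - p - 1 degrees of freedom.
    """

    response_name: str
    predictor_names: tuple[str, ...]
    coefficients: Mapping[str, CoefEstimate]
    r2: float
    adj_r2: float
    n_used: int
    residual_sd: float

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"term": k, "estimate": c.estimate, "se": c.se,
             "t": c.t, "p": c.p}
            for k, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return df[list(cols)].dropna()


def fit_ols(table: CohortTable | pd.DataFrame, response: str,
            predictors: Sequence[str], *,
            standardized: bool = False) -> OlsFit:
    """Fit response ~ intercept + predictors by ordinary least squares.

    Complete-case: rows missing any involved value are dropped and the
    remainder counted in ``n_used``.

    Raises
    ------
    RankDeficientError
        If the design matrix is collinear to machine precision, naming
        the offending column(s).
    ValueError
        If fewer than p + 2 complete cases remain.
    """
    df = table.df if isinstance(table, CohortTable) else table
    predictors = tuple(predictors)
    data = _complete_cases(df, [response, *predictors])
    n, p = len(data), len(predictors)
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} complete cases for {p} predictor(s), "
            f"got {n}")
    X = sm.add_constant(data[list(predictors)].to_numpy(dtype=float),
                        has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, predictors)
        raise RankDeficientError(
            f"collinear design: column(s) {bad} are linearly dependent "
            "(constant or exact linear combinations)")
    y = data[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    names = ("const", *predictors)
    std_betas = {}
    if standardized:
        sy = y.std(ddof=1)
        for j, name in enumerate(predictors):
            sx = data[name].std(ddof=1)
            std_betas[name] = res.params[j + 1] * sx / sy
    coefs = {
        name: CoefEstimate(
            estimate=float(res.params[j]),
            se=float(res.bse[j]),
            t=float(res.tvalues[j]),
            p=float(res.pvalues[j]),
            std_estimate=std_betas.get(name),
        )
        for j, name in enumerate(names)
    }
    return OlsFit(
        response_name=response,
        predictor_names=predictors,
        coefficients=coefs,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n_used=n,
        residual_sd=float(np.sqrt(res.mse_resid)) if n > p + 1 else 0.0,
    )


def _collinear_columns(X: np.ndarray, predictors: tuple[str, ...]) -> list[str]:
    """Name predictor columns whose removal restores full rank."""
    full = X.shape[1]
    bad = []
    for j in range(1, full):  # never blame the intercept
        Xr = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
            bad.append(predictors[j - 1])
    return bad or list(predictors)


@dataclass(frozen=True)
class ModelSuite:
    """The three-model analysis with Holm-corrected primary p-values."""

    model_a: OlsFit                 # angle ~ age
    model_b: OlsFit                 # angle ~ aub
    model_b_reverse: OlsFit         # aub ~ angle (same R2)
    model_c: OlsFit                 # angle ~ age + aub
    holm_adjusted_p: Mapping[str, float] = field(default_factory=dict)

    @property
    def r2_angle_aub(self) -> float:
        """Direction-invariant R-squared of the simple angle-breadth fit."""
        return self.model_b.r2


def model_suite(table: CohortTable, *,
                angle_col: str = "lateral_angle_deg",
                age_col: str = "age_years",
                aub_col: str = "aub_mm") -> ModelSuite:
    """Fit the three-model suite and Holm-adjust its primary p-values.

    The primary tests are the age slope of model A, the breadth slope of
    model B, and the age and breadth partial slopes of model C.
    """
    model_a = fit_ols(table, angle_col, [age_col])
    model_b = fit_ols(table, angle_col, [aub_col])
    model_b_rev = fit_ols(table, aub_col, [angle_col])
    model_c = fit_ols(table, angle_col, [age_col, aub_col])
    raw = {
        "model_a:age": model_a.coefficients[age_col].p,
        "model_b:aub": model_b.coefficients[aub_col].p,
        "model_c:age": model_c.coefficients[age_col].p,
        "model_c:aub": model_c.coefficients[aub_col].p,
    }
    adj = holm_adjust(list(raw.values()))
    return ModelSuite(
        model_a=model_a,
        model_b=model_b,
        model_b_reverse=model_b_rev,
        model_c=model_c,
        holm_adjusted_p=dict(zip(raw.keys(), adj)),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a
    monotone cumulative maximum, cap at 1.  Uniformly no smaller than the
    raw p-values; equals Bonferroni for the smallest.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, alpha=0.05, method="holm")
    return [float(v) for v in adj]
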