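"""Sex classification assessment: ROC/AUC, logistic regression, cut-offs.

The question is whether a single osteometric score (lateral angle or
biauricular breadth) separates the sexes.  Convention throughout: the
positive class is female with higher-score -> positive orientation,
because adult females show larger lateral angles; an AUC below 0.5 is
reported as-is, never flipped.  AUC uses trapezoidal integration of the
tie-grouped threshold sweep, which equals the Mann-Whitney probability
with half-credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core_data import CohortTable
from .regression import CoefEstimate

__all__ = ["RocResult", "LogisticFit", "CutoffReport", "roc_curve",
           "fit_logistic", "classify_cutoff", "PerfectSeparationError"]


class PerfectSeparationError(RuntimeError):
    """Logistic MLE does not exist: the predictor perfectly separates."""


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep of true/false-positive rates plus the area.

    The stored curve starts at (0, 0) and ends at (1, 1); equal scores
    are grouped into a single step.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_label: str
    orientation: str = "higher-score->positive"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_curve(table: CohortTable | pd.DataFrame, score: str,
              positive: str = "F", *, label_col: str = "sex") -> RocResult:
    """ROC curve of a score column against the sex label.

    Complete cases only.  With fewer than two distinct scores the curve
    degenerates to the chance diagonal (AUC 0.5).

    Raises
    ------
    ValueError
        If only one class is present among complete cases.
    """
    df = table.df if isinstance(table, CohortTable) else table
    data = df[[label_col, score]].dropna()
    y = (data[label_col] == positive).to_numpy()
    if y.all() or not y.any():
        raise ValueError(
            f"need both classes among complete cases of {score!r}; "
            f"only {'positive' if y.all() else 'negative'} rows present")
    s = data[score].to_numpy(dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        positive_label=positive,
    )


@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression fit (maximum likelihood, IRLS)."""

    response_name: str
    predictor_names: tuple[str, ...]
    coefficients: Mapping[str, CoefEstimate]
    converged: bool
    n_used: int
    log_likelihood: float

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        c = self.coefficients[term]
        z = norm.ppf(0.5 + level / 2)
        return (c.estimate - z * c.se, c.estimate + z * c.se)


def fit_logistic(table: CohortTable | pd.DataFrame, label: str,
                 predictor: str, *, positive: str = "F",
                 tol: float = 1e-8, maxiter: int = 100) -> LogisticFit:
    """Binary logistic regression of a sex label on one predictor.

    Deterministic (no random initialisation); iteratively reweighted
    least squares to ``tol`` on the coefficient change.

    Raises
    ------
    PerfectSeparationError
        If the predictor perfectly separates the classes (the MLE
        diverges); silent huge estimates are never returned.
    """
    df = table.df if isinstance(table, CohortTable) else table
    data = df[[label, predictor]].dropna()
    y = (data[label] == positive).astype(float).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    x = data[predictor].to_numpy(dtype=float)
    # perfect separation check: some threshold splits the classes exactly
    if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
        raise PerfectSeparationError(
            f"{predictor!r} perfectly separates the classes; "
            "logistic MLE does not exist")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton",
                                     tol=tol, maxiter=maxiter)
        except Exception as exc:  # statsmodels' own separation error
            raise PerfectSeparationError(str(exc)) from exc
    if not np.all(np.isfinite(res.bse)):
        raise PerfectSeparationError(
            "non-finite standard errors: quasi-separated design")
    names = ("const", predictor)
    coefs = {
        name: CoefEstimate(
            estimate=float(res.params[j]), se=float(res.bse[j]),
            t=float(res.tvalues[j]), p=float(res.pvalues[j]))
        for j, name in enumerate(names)
    }
    return LogisticFit(
        response_name=label,
        predictor_names=(predictor,),
        coefficients=coefs,
        converged=bool(res.mle_retvals.get("converged", False)),
        n_used=len(data),
        log_likelihood=float(res.llf),
    )


@dataclass(frozen=True)
class CutoffReport:
    """Fixed-threshold sex classification (e.g. the 45-degree rule).

    Rule: score strictly above the cut-off -> F; at or below -> M.
    """

    cutoff: float
    rule: str
    n_used: int
    accuracy: float
    accuracy_f: float
    accuracy_m: float
    confusion: Mapping[str, int]  # keys "tf", "fm_as_m", "tm", "fm_as_f"


def classify_cutoff(table: CohortTable | pd.DataFrame, score: str,
                    cutoff: float = 45.0, *,
                    label_col: str = "sex") -> CutoffReport:
    """Apply a fixed cut-off rule (score > cutoff -> F, else M).

    The boundary convention follows the classical rule: a score exactly
    at the cut-off classifies as male.
    """
    df = table.df if isinstance(table, CohortTable) else table
    data = df[[label_col, score]].dropna()
    truth = data[label_col].to_numpy()
    pred = np.where(data[score].to_numpy(dtype=float) > cutoff, "F", "M")
    n = len(data)
    tf = int(((truth == "F") & (pred == "F")).sum())
    tm = int(((truth == "M") & (pred == "M")).sum())
    n_f = int((truth == "F").sum())
    n_m = n - n_f
    return CutoffReport(
        cutoff=float(cutoff),
        rule="score > cutoff -> F, else M",
        n_used=n,
        accuracy=(tf + tm) / n if n else float("nan"),
        accuracy_f=tf / n_f if n_f else float("nan"),
        accuracy_m=tm / n_m if n_m else float("nan"),
        confusion={"true_f": tf, "f_as_m": n_f - tf,
                   "true_m": tm, "m_as_f": n_m - tm},
    )


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximising tpr - fpr (Youden index), for convenience."""
    j = roc.tpr - roc.fpr
    return float(roc.thresholds[int(np.argmax(j))])
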