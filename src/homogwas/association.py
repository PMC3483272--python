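"""Association-testing strategies for weighted case-control cohorts.

Four strategies are compared throughout: the Fisher exact test on the
original cohort, the Fisher exact test on the homogenized (weighted)
cohort, logistic regression with the leading PCs as covariates, and
weighted logistic regression with PCs using the homogenized weights.
ROC curves over collections of causal and null genotypes summarize the
trade-off between true- and false-positive rates across significance
thresholds.

Genotypes are binary subject labels coded 0 = A, 1 = ~A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .contingency import ContingencyTable, fisher_exact_p, odds_ratio
from .spheres import Cohort

__all__ = [
    "AssocResult",
    "ROCCurve",
    "fisher_assoc",
    "logistic_pc_assoc",
    "roc_points",
    "auc_se",
]

METHODS = ("fisher_original", "fisher_homogenized", "logistic_pc", "logistic_pc_weighted")


@dataclass(frozen=True)
class AssocResult:
    """Outcome of one genotype-phenotype association test."""

    method: str
    p_value: float
    effect: float  # log-OR (Fisher) or genotype coefficient (logistic)
    genotype_id: str = "g"

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def genotype_table(genotype: np.ndarray, cohort: Cohort) -> ContingencyTable:
    """Weighted phenotype-by-genotype 2x2 table (a = diseased & A)."""
    g = np.asarray(genotype)
    if g.shape[0] != cohort.n:
        raise ValueError("genotype must be defined for every subject")
    not_a = g.astype(bool)
    w, dis = cohort.weights, cohort.diseased
    a = float(np.sum(w * (dis & ~not_a)))
    b = float(np.sum(w * (dis & not_a)))
    c = float(np.sum(w * (~dis & ~not_a)))
    d = float(np.sum(w * (~dis & not_a)))
    return ContingencyTable(a, b, c, d)


def fisher_assoc(
    genotype: np.ndarray, cohort: Cohort, genotype_id: str = "g", method: str = "fisher"
) -> AssocResult:
    """Fisher exact association test on the (weight-rounded) 2x2 table.

    Builds the weighted phenotype-by-genotype table, rounds cells to the
    nearest integer, and returns the two-sided Fisher p with the Haldane
    log-OR of the rounded table. A single-genotype input yields a zero
    column margin and hence p = 1.
    """
    table = genotype_table(genotype, cohort).rounded()
    return AssocResult(
        method=method,
        p_value=fisher_exact_p(table),
        effect=math.log(odds_ratio(table, haldane=True)),
        genotype_id=genotype_id,
    )


def logistic_pc_assoc(
    genotype: np.ndarray,
    cohort: Cohort,
    n_pcs: int = 3,
    use_weights: bool = False,
    genotype_id: str = "g",
    method: str | None = None,
) -> AssocResult:
    """Logistic regression of phenotype on genotype plus leading PCs.

    Fits phenotype ~ intercept + genotype + PC1..PCn by maximum likelihood
    (frequency-weighted by the cohort weights when ``use_weights``) and
    returns the Wald p-value and coefficient of the genotype term. Perfect
    separation is reported as the boundary p-value (smallest positive
    float) with a convergence warning rather than an exception.
    """
    g = np.asarray(genotype, dtype=float)
    if g.shape[0] != cohort.n:
        raise ValueError("genotype must be defined for every subject")
    if n_pcs > cohort.k:
        raise ValueError(f"n_pcs={n_pcs} exceeds available PC columns ({cohort.k})")
    y = cohort.diseased.astype(float)
    if len(np.unique(y)) < 2 or len(np.unique(g)) < 2:
        raise ValueError("both phenotypes and both genotypes must be present")
    X = np.column_stack([np.ones(cohort.n), g, cohort.coords[:, :n_pcs]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear genotype/PCs)")
    kwargs = {"freq_weights": cohort.weights} if use_weights else {}
    if method is None:
        method = "logistic_pc_weighted" if use_weights else "logistic_pc"
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial(), **kwargs).fit()
        p = float(res.pvalues[1])
        effect = float(res.params[1])
    except PerfectSeparationError:
        warnings.warn(
            "perfect separation in logistic fit; reporting boundary p-value",
            stacklevel=2,
        )
        p = float(np.finfo(float).tiny)
        effect = math.inf
    if not np.isfinite(p) or p <= 0:
        p = float(np.finfo(float).tiny)
    return AssocResult(
        method=method, p_value=min(p, 1.0), effect=effect, genotype_id=genotype_id
    )


def roc_points(
    results_positive: list[AssocResult], results_negative: list[AssocResult]
) -> ROCCurve:
    """ROC curve over p-value thresholds, with trapezoidal AUC.

    A genotype is called significant when its p-value is at or below the
    threshold; sweeping the threshold over the observed p-values gives TPR
    (fraction of positives called) against FPR (fraction of negatives
    called). The curve runs from (0, 0) to (1, 1).
    """
    if not results_positive or not results_negative:
        raise ValueError("both result lists must be nonempty")
    p = np.array([r.p_value for r in results_positive + results_negative])
    labels = np.array([1] * len(results_positive) + [0] * len(results_negative))
    fpr, tpr, _ = _sk_roc_curve(labels, -p)  # score = -p: smaller p = stronger call
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def auc_se(auc_value: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    q1 = auc_value / (2 - auc_value)
    q2 = 2 * auc_value**2 / (1 + auc_value)
    var = (
        auc_value * (1 - auc_value)
        + (n_pos - 1) * (q1 - auc_value**2)
        + (n_neg - 1) * (q2 - auc_value**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))
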