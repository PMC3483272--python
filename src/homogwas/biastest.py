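"""The potential p-value bias test.

A hypothetical genotype carried by exactly the subjects inside a spatial
sphere, and by nobody outside it, is the most extreme genotype associated
with the subpopulation in that sphere. If the diseased/healthy ratio inside
the sphere differs from the ratio outside, such a genotype produces a
false-positive Fisher signal. Scanning all subject-centered spheres over a
ladder of sphere weights and recording the smallest Fisher p-value yields a
cohort-level diagnostic of structure-driven false-positive potential: the
smaller the minimum p, the worse the bias potential.

Fisher tests are performed on the sphere contingency tables rounded to the
nearest integer (the identity on unit-weight cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .contingency import _fisher_int
from .homogenize import HomogenizationParams, homogenize, num_cycles
from .spheres import Cohort, NeighborIndex, all_sphere_tables, build_neighbor_index

__all__ = [
    "DEFAULT_SPHERE_WEIGHTS",
    "BiasTestReport",
    "potential_pvalue_bias_test",
    "weight_reduction_sweep",
    "PotentialPValueBias",
]

#: sphere-weight ladder of the diagnostic (spans local to near-global scales)
DEFAULT_SPHERE_WEIGHTS: tuple[float, ...] = (25, 50, 100, 200, 400, 800, 1600)


@dataclass
class BiasTestReport:
    """Minimum Fisher p-values over all subject-centered spheres.

    Attributes
    ----------
    per_weight : dict
        Sphere weight -> minimum p over all spheres of that weight.
    overall : float
        Minimum over all weights (the test value).
    argmin : tuple
        ``(sphere_weight, center_id)`` attaining the overall minimum; ties
        go to the smaller weight, then the earlier subject.
    """

    per_weight: dict[float, float]
    overall: float
    argmin: tuple[float, str]

    def to_dict(self) -> dict:
        return {
            "per_weight": {str(k): v for k, v in self.per_weight.items()},
            "overall": self.overall,
            "argmin": {"sphere_weight": self.argmin[0], "center_id": self.argmin[1]},
        }


def potential_pvalue_bias_test(
    cohort: Cohort,
    sphere_weights: tuple[float, ...] = DEFAULT_SPHERE_WEIGHTS,
    index: NeighborIndex | None = None,
) -> BiasTestReport:
    """Run the potential p-value bias test on a (possibly weighted) cohort.

    Sphere weights exceeding the total cohort weight are skipped with a
    warning so the default ladder works on small cohorts.
    """
    sphere_weights = tuple(sphere_weights)
    if not sphere_weights:
        raise ValueError("sphere_weights must not be empty")
    if index is None:
        index = build_neighbor_index(cohort)
    total = cohort.total_weight
    usable = [w for w in sphere_weights if w <= total]
    skipped = [w for w in sphere_weights if w > total]
    if skipped:
        warnings.warn(
            f"sphere weights {skipped} exceed the total cohort weight {total:.4g}; skipped",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("every requested sphere weight exceeds the total cohort weight")

    per_weight: dict[float, float] = {}
    best: tuple[float, float, str] | None = None  # (p, weight, center_id)
    for W in usable:
        a, b, c, d, _ = all_sphere_tables(W, cohort, index)
        p_min, center_min = _min_fisher(a, b, c, d, cohort)
        per_weight[float(W)] = p_min
        if best is None or p_min < best[0]:
            best = (p_min, float(W), center_min)
    assert best is not None
    return BiasTestReport(
        per_weight=per_weight, overall=best[0], argmin=(best[1], best[2])
    )


def _min_fisher(a, b, c, d, cohort: Cohort) -> tuple[float, str]:
    cells = np.stack([a, b, c, d], axis=1)
    rounded = np.floor(cells + 0.5).astype(int)  # halves away from zero, cells >= 0
    p_best, i_best = 2.0, -1
    for i, (ai, bi, ci, di) in enumerate(rounded):
        p = _fisher_int(int(ai), int(bi), int(ci), int(di))
        if p < p_best:
            p_best, i_best = p, i
    return p_best, str(cohort.ids[i_best])


def weight_reduction_sweep(
    cohort: Cohort,
    fractions: tuple[float, ...],
    params: HomogenizationParams | None = None,
    sphere_weights: tuple[float, ...] = DEFAULT_SPHERE_WEIGHTS,
    index: NeighborIndex | None = None,
) -> dict[float, BiasTestReport]:
    """Bias test after homogenizing at each weight-reduction fraction.

    Used to select the weight-reduction parameter: the bias-test value
    typically improves steeply then flattens, and the knee is a good
    operating point. Because the fraction only sets the cycle count, a
    single run at the largest fraction is performed and every smaller
    fraction is replayed exactly from a prefix of its knock-down log.
    """
    params = params or HomogenizationParams()
    fractions = tuple(fractions)
    if not fractions:
        raise ValueError("fractions must not be empty")
    if index is None:
        index = build_neighbor_index(cohort)
    f_max = max(fractions)
    full = homogenize(
        cohort,
        HomogenizationParams(
            sphere_weight=params.sphere_weight,
            knockdown_weight=params.knockdown_weight,
            weight_reduction=f_max,
        ),
        index=index,
    )
    knocked_ids = [r.knocked_id for r in full.log]
    total = cohort.total_weight
    out: dict[float, BiasTestReport] = {}
    for f in fractions:
        t = min(num_cycles(total, f, params.knockdown_weight), len(knocked_ids))
        work = cohort.copy()
        for sid in knocked_ids[:t]:
            work.weights[work.index_of(sid)] = params.knockdown_weight
        out[float(f)] = potential_pvalue_bias_test(work, sphere_weights, index)
    return out


class PotentialPValueBias(BaseEstimator):
    """Estimator interface to the potential p-value bias test.

    Parameters
    ----------
    sphere_weights : tuple of float
        Ladder of sphere weights to scan.

    Attributes
    ----------
    per_weight_ : dict
    overall_ : float
    argmin_ : tuple
    """

    def __init__(self, sphere_weights: tuple[float, ...] = DEFAULT_SPHERE_WEIGHTS):
        self.sphere_weights = sphere_weights

    def fit(self, X, y, sample_weight=None):
        """Evaluate the diagnostic on PC coordinates ``X`` and phenotype ``y``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(bool)
        cohort = Cohort(
            ids=np.array([str(i) for i in range(X.shape[0])], dtype=object),
            diseased=y,
            coords=X,
            weights=sample_weight,
        )
        report = potential_pvalue_bias_test(cohort, tuple(self.sphere_weights))
        self.per_weight_ = report.per_weight
        self.overall_ = report.overall
        self.argmin_ = report.argmin
        self.report_ = report
        return self
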