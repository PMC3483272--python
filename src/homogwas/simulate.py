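"""Synthetic cohorts and genotype-assignment schemes for the simulation study.

The generator emulates the statistical structure of a structured GWAS
cohort: a point cloud in 3-dimensional PC ancestry space drawn from a
Gaussian mixture, a rectangular "box" region (one ancestry subgroup) where
the diseased/healthy assignment is imbalanced (0.6/0.4 against 0.5/0.5 in
the population at large), and five genotype-assignment schemes:

* three *true-positive* schemes -- genotype ~A assigned with a larger
  probability to diseased than to healthy subjects, uniformly in space
  (probabilities 0.57/0.50, 0.15/0.10, 0.06/0.03; population ORs 1.33,
  1.59, 2.06);
* two *false-positive* schemes -- genotype depends only on box membership,
  never on phenotype (0.90/0.10 and 0.80/0.20 inside/outside), so the
  population OR is 1 within each stratum yet the box's phenotype imbalance
  creates a spurious pooled association;
* one *false-negative* scheme -- a genuine within-stratum association
  (OR 1.65 above and below the PC2 = -2.68 line) concealed in the pooled
  cohort by opposite allele prevalences in the two strata
  (probabilities 0.08/0.05 below the line, 0.95/0.92 above).

Each scheme is replicated 500 times in the full study. ``run_study`` chains
cohort simulation, homogenization (sphere weight 30, knocked-down weight
0.2, 9% weight reduction) and the four association strategies into the ROC
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .association import AssocResult, ROCCurve, fisher_assoc, logistic_pc_assoc, roc_points
from .homogenize import HomogenizationParams, HomogenizationResult, homogenize
from .spheres import Cohort

__all__ = [
    "MixtureComponent",
    "Box",
    "StructuredCohortSpec",
    "GenotypeScheme",
    "simulate_cohort",
    "expected_or",
    "gen_true_positive",
    "gen_false_positive",
    "gen_false_negative",
    "default_schemes",
    "run_study",
    "StudyResult",
    "TRUE_POSITIVE_PRESETS",
    "FALSE_POSITIVE_PRESETS",
    "FALSE_NEGATIVE_PROBS",
    "PC2_LINE",
]

#: (p(~A | diseased), p(~A | healthy)) for the three true-positive schemes
TRUE_POSITIVE_PRESETS: tuple[tuple[float, float], ...] = (
    (0.57, 0.50),
    (0.15, 0.10),
    (0.06, 0.03),
)
#: (p(~A | in box), p(~A | outside)) for the two false-positive schemes
FALSE_POSITIVE_PRESETS: tuple[tuple[float, float], ...] = ((0.90, 0.10), (0.80, 0.20))
#: (below & diseased, below & healthy, above & diseased, above & healthy)
FALSE_NEGATIVE_PROBS: tuple[float, float, float, float] = (0.08, 0.05, 0.95, 0.92)
#: PC2 threshold of the false-negative scheme's stratum line
PC2_LINE: float = -2.68


@dataclass(frozen=True)
class MixtureComponent:
    mean: tuple[float, ...]
    cov: tuple[float, ...]  # per-axis variances (diagonal covariance)
    proportion: float


@dataclass(frozen=True)
class Box:
    """Axis-aligned region; +/-inf bounds leave an axis unconstrained."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def contains(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((coords >= lo) & (coords <= hi), axis=1)


def _default_components() -> tuple[MixtureComponent, ...]:
    # Three overlapping ancestry components forming a continuous cloud in
    # which the box is a *middle band* of PC2: the general cloud lies above
    # the box, the box component inside it (straddling the PC2 stratum
    # line), and a third arm below it. With population on both sides of the
    # band, box membership is non-monotone in the PCs, so linear PC
    # covariates can only partially absorb box-shaped confounding -- the
    # situation the study design describes (the stratum line crosses the
    # box region; the below-line population extends beyond the box).
    return (
        MixtureComponent(mean=(0.0, 2.0, 0.0), cov=(9.0, 2.25, 1.0), proportion=0.62),
        MixtureComponent(mean=(2.5, -2.5, 0.0), cov=(2.25, 0.64, 1.0), proportion=0.18),
        MixtureComponent(mean=(1.5, -6.5, 0.3), cov=(4.0, 1.0, 1.0), proportion=0.20),
    )


DEFAULT_BOX = Box(lower=(-2.0, -4.8, -np.inf), upper=(7.0, -0.2, np.inf))


@dataclass(frozen=True)
class StructuredCohortSpec:
    """Generative description of a structured synthetic cohort.

    Defaults mirror the study conditions: ~4000 subjects (the application
    cohort held 3986), a 0.6/0.4 diseased/healthy chance inside the box
    against 0.5/0.5 elsewhere, all weights 1.
    """

    n_subjects: int = 4000
    components: tuple[MixtureComponent, ...] = field(default_factory=_default_components)
    box: Box = DEFAULT_BOX
    p_diseased_in_box: float = 0.6
    p_diseased_outside: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        props = [c.proportion for c in self.components]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        for p in (self.p_diseased_in_box, self.p_diseased_outside):
            if not (0 < p < 1):
                raise ValueError("phenotype probabilities must lie in (0, 1)")


def simulate_cohort(spec: StructuredCohortSpec | None = None) -> Cohort:
    """Draw a structured cohort: mixture coordinates + box-imbalanced labels."""
    spec = spec or StructuredCohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    props = np.array([c.proportion for c in spec.components])
    comp = rng.choice(len(spec.components), size=n, p=props)
    k = len(spec.components[0].mean)
    coords = np.empty((n, k))
    for ci, c in enumerate(spec.components):
        m = comp == ci
        coords[m] = rng.normal(
            loc=np.asarray(c.mean), scale=np.sqrt(np.asarray(c.cov)), size=(int(m.sum()), k)
        )
    in_box = spec.box.contains(coords)
    if not in_box.any():
        warnings.warn("box region contains no subjects", stacklevel=2)
    p_dis = np.where(in_box, spec.p_diseased_in_box, spec.p_diseased_outside)
    diseased = rng.random(n) < p_dis
    return Cohort(
        ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        diseased=diseased,
        coords=coords,
    )


def expected_or(p_notA_diseased: float, p_notA_healthy: float) -> float:
    """Population odds ratio implied by phenotype-conditional ~A probabilities.

    ``[p_d/(1-p_d)] / [p_h/(1-p_h)]``: the OR of the ~A genotype between
    diseased and healthy subjects.
    """
    for p in (p_notA_diseased, p_notA_healthy):
        if not (0 < p < 1):
            raise ValueError(f"probabilities must lie strictly in (0, 1), got {p}")
    return (p_notA_diseased / (1 - p_notA_diseased)) / (
        p_notA_healthy / (1 - p_notA_healthy)
    )


def _draw(prob: np.ndarray, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """n_reps independent genotype vectors; entry 1 = ~A with given prob."""
    return (rng.random((n_reps, prob.shape[0])) < prob).astype(np.int8)


def gen_true_positive(
    cohort: Cohort,
    p_notA_diseased: float,
    p_notA_healthy: float,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genotypes associated with phenotype uniformly across space."""
    rng = np.random.default_rng(seed)
    prob = np.where(cohort.diseased, p_notA_diseased, p_notA_healthy)
    return _draw(prob, n_reps, rng)


def gen_false_positive(
    cohort: Cohort,
    p_notA_in_box: float,
    p_notA_outside: float,
    box: Box = DEFAULT_BOX,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null genotypes (OR = 1 per stratum) tagging the box subpopulation."""
    rng = np.random.default_rng(seed)
    in_box = box.contains(cohort.coords)
    prob = np.where(in_box, p_notA_in_box, p_notA_outside)
    return _draw(prob, n_reps, rng)


def gen_false_negative(
    cohort: Cohort,
    probs: tuple[float, float, float, float] = FALSE_NEGATIVE_PROBS,
    pc2_line: float = PC2_LINE,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Within-stratum-associated genotypes concealed by opposite prevalences.

    ``probs`` = (below & diseased, below & healthy, above & diseased,
    above & healthy) probabilities of ~A; strata split at PC2 < ``pc2_line``.
    """
    rng = np.random.default_rng(seed)
    below = cohort.coords[:, 1] < pc2_line
    if not below.any() or below.all():
        raise ValueError("both strata of the PC2 line must be nonempty")
    p_bd, p_bh, p_ad, p_ah = probs
    prob = np.where(
        below,
        np.where(cohort.diseased, p_bd, p_bh),
        np.where(cohort.diseased, p_ad, p_ah),
    )
    return _draw(prob, n_reps, rng)


@dataclass(frozen=True)
class GenotypeScheme:
    """A named genotype-assignment rule with its implied population OR."""

    name: str
    kind: str  # "true_positive" | "false_positive" | "false_negative"
    params: tuple[float, ...]
    implied_or: float

    def generate(
        self, cohort: Cohort, n_reps: int, seed: int | np.random.Generator
    ) -> np.ndarray:
        if self.kind == "true_positive":
            return gen_true_positive(cohort, *self.params, n_reps=n_reps, seed=seed)
        if self.kind == "false_positive":
            return gen_false_positive(cohort, *self.params, n_reps=n_reps, seed=seed)
        if self.kind == "false_negative":
            return gen_false_negative(cohort, self.params, n_reps=n_reps, seed=seed)
        raise ValueError(f"unknown scheme kind {self.kind!r}")

    @property
    def is_null(self) -> bool:
        """True for schemes whose population OR is 1 (ROC negative class)."""
        return self.implied_or == 1.0


def default_schemes() -> list[GenotypeScheme]:
    """The five genotype-assignment schemes of the simulation study."""
    schemes = [
        GenotypeScheme(
            name=f"tp_{pd:g}_{ph:g}",
            kind="true_positive",
            params=(pd, ph),
            implied_or=expected_or(pd, ph),
        )
        for pd, ph in TRUE_POSITIVE_PRESETS
    ]
    schemes += [
        GenotypeScheme(
            name=f"fp_{pi:g}_{po:g}", kind="false_positive", params=(pi, po), implied_or=1.0
        )
        for pi, po in FALSE_POSITIVE_PRESETS
    ]
    schemes.append(
        GenotypeScheme(
            name="fn_strata",
            kind="false_negative",
            params=FALSE_NEGATIVE_PROBS,
            implied_or=expected_or(FALSE_NEGATIVE_PROBS[0], FALSE_NEGATIVE_PROBS[1]),
        )
    )
    return schemes


@dataclass
class StudyResult:
    """Everything the simulation study produces."""

    cohort: Cohort
    homog: HomogenizationResult
    results: dict[str, list[AssocResult]]  # method -> one result per genotype
    scheme_kinds: dict[str, str]  # genotype_id -> scheme kind
    positive_ids: set[str]  # genotypes with population OR != 1
    rocs: dict[str, ROCCurve]


def run_study(
    spec: StructuredCohortSpec | None = None,
    schemes: list[GenotypeScheme] | None = None,
    homog_params: HomogenizationParams | None = None,
    n_reps: int = 500,
    seed: int = 0,
    n_pcs: int = 3,
) -> StudyResult:
    """Full simulation study: simulate, homogenize, test, build ROC curves.

    The ROC positive class contains every genotype simulated with a
    population OR different from 1 (true-positive and false-negative
    schemes); the negative class contains the null (false-positive)
    schemes.
    """
    spec = spec or StructuredCohortSpec()
    schemes = schemes if schemes is not None else default_schemes()
    homog_params = homog_params or HomogenizationParams(
        sphere_weight=30.0, knockdown_weight=0.2, weight_reduction=0.09
    )
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(spec)
    homog = homogenize(cohort, homog_params)
    weighted = cohort.copy()
    weighted.weights = homog.final_weights.copy()

    results: dict[str, list[AssocResult]] = {m: [] for m in (
        "fisher_original", "fisher_homogenized", "logistic_pc", "logistic_pc_weighted"
    )}
    scheme_kinds: dict[str, str] = {}
    positive_ids: set[str] = set()
    for scheme in schemes:
        genos = scheme.generate(cohort, n_reps, rng)
        for r, g in enumerate(genos):
            gid = f"{scheme.name}:rep{r}"
            scheme_kinds[gid] = scheme.kind
            if not scheme.is_null:
                positive_ids.add(gid)
            results["fisher_original"].append(
                fisher_assoc(g, cohort, genotype_id=gid, method="fisher_original")
            )
            results["fisher_homogenized"].append(
                fisher_assoc(g, weighted, genotype_id=gid, method="fisher_homogenized")
            )
            results["logistic_pc"].append(
                logistic_pc_assoc(g, cohort, n_pcs=n_pcs, use_weights=False,
                                  genotype_id=gid, method="logistic_pc")
            )
            results["logistic_pc_weighted"].append(
                logistic_pc_assoc(g, weighted, n_pcs=n_pcs, use_weights=True,
                                  genotype_id=gid, method="logistic_pc_weighted")
            )

    rocs = {
        m: roc_points(
            [r for r in rs if r.genotype_id in positive_ids],
            [r for r in rs if r.genotype_id not in positive_ids],
        )
        for m, rs in results.items()
    }
    return StudyResult(
        cohort=cohort,
        homog=homog,
        results=results,
        scheme_kinds=scheme_kinds,
        positive_ids=positive_ids,
        rocs=rocs,
    )
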