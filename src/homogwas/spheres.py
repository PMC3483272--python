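"""Subject-centered Euclidean balls ("spheres") in PC ancestry space.

A sphere is characterized by the total statistical weight of the subjects in
its interior rather than by its spatial radius: the sphere centered on a
subject at requested weight ``W`` is the smallest closed ball whose member
weights sum to at least ``W``. Its *sphere OR* is the odds ratio of the 2x2
table crossing phenotype with sphere membership -- the OR an idealized
genotype carried by exactly the sphere's members would show.

All distances are Euclidean on the first k principal-component scores.
Neighbor orderings are computed once (weights change across homogenization
cycles, positions do not) and reused; ties in distance are broken by subject
input order, and all subjects at exactly the final radius are included so
membership does not depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .contingency import ContingencyTable, odds_ratio

__all__ = [
    "Cohort",
    "NeighborIndex",
    "Sphere",
    "build_neighbor_index",
    "sphere_at",
    "sphere_table",
    "all_sphere_tables",
    "all_sphere_ors",
]


def _seqsum(x: np.ndarray) -> float:
    """Strict left-to-right sum, so prefix sums and totals agree bitwise."""
    if x.size == 0:
        return 0.0
    return float(np.cumsum(x)[-1])


@dataclass
class Cohort:
    """Subjects with phenotype labels, PC coordinates and statistical weights.

    Parameters
    ----------
    ids : ndarray of str
        Subject identifiers, in file/input order.
    diseased : ndarray of bool
        True for diseased (case) subjects, False for healthy (control).
    coords : ndarray, shape (n, k)
        Coordinates in the k-dimensional PC ancestry space.
    weights : ndarray of float, optional
        Statistical weights in (0, 1]; defaults to all ones.
    fids : ndarray of str, optional
        Family IDs (PLINK dialect); default equal to ``ids``.
    """

    ids: np.ndarray
    diseased: np.ndarray
    coords: np.ndarray
    weights: np.ndarray | None = None
    fids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.diseased = np.asarray(self.diseased, dtype=bool)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = self.ids.shape[0]
        if self.coords.shape[0] != n or self.diseased.shape[0] != n:
            raise ValueError("ids, diseased and coords must agree on subject count")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float).copy()
            if self.weights.shape[0] != n:
                raise ValueError("weights length mismatch")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise ValueError("weights must lie in (0, 1]")
        if self.fids is None:
            self.fids = self.ids.copy()
        else:
            self.fids = np.asarray(self.fids, dtype=object)

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def total_weight(self) -> float:
        return _seqsum(self.weights)

    @property
    def total_diseased_weight(self) -> float:
        return _seqsum(self.weights * self.diseased)

    @property
    def total_healthy_weight(self) -> float:
        return _seqsum(self.weights * ~self.diseased)

    def copy(self) -> "Cohort":
        return Cohort(
            ids=self.ids.copy(),
            diseased=self.diseased.copy(),
            coords=self.coords.copy(),
            weights=self.weights.copy(),
            fids=self.fids.copy(),
        )

    def index_of(self, subject_id: str) -> int:
        hits = np.flatnonzero(self.ids == subject_id)
        if hits.size != 1:
            raise KeyError(f"subject id {subject_id!r} not unique or not found")
        return int(hits[0])


class NeighborIndex:
    """Per-subject distance-sorted neighbor lists, fixed once per cohort.

    Attributes
    ----------
    order : ndarray of int, shape (n, n)
        ``order[i]`` lists all subject indices by nondecreasing distance from
        subject ``i`` (self first); distance ties keep input order.
    sorted_dist : ndarray of float, shape (n, n)
        Distances along each ordered list.
    """

    def __init__(self, coords: np.ndarray) -> None:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        dist = cdist(coords, coords)
        # stable sort -> ties in distance broken by subject input order
        self.order = np.argsort(dist, axis=1, kind="stable").astype(np.int64)
        self.sorted_dist = np.take_along_axis(dist, self.order, axis=1)
        self.n = coords.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.order[i]


def build_neighbor_index(cohort: Cohort) -> NeighborIndex:
    """Distance-sorted neighbor lists for every subject of the cohort."""
    return NeighborIndex(cohort.coords)


@dataclass
class Sphere:
    """A closed ball around a subject holding at least the requested weight.

    ``members`` are subject indices in nondecreasing distance from the
    center (center itself first).
    """

    center: int
    members: np.ndarray
    radius: float
    cohort_weight: float
    requested_weight: float = field(default=float("nan"))

    @property
    def n_members(self) -> int:
        return self.members.shape[0]


def sphere_at(
    center: int, W: float, cohort: Cohort, index: NeighborIndex | None = None
) -> Sphere:
    """Smallest closed ball centered on ``center`` with weight >= ``W``.

    Walks the center's distance-sorted neighbor list accumulating weights
    until the running sum reaches ``W``; every subject at exactly the final
    radius is then included (closed ball).
    """
    if index is None:
        index = build_neighbor_index(cohort)
    total = cohort.total_weight
    if W > total:
        raise ValueError(f"requested sphere weight {W} exceeds total cohort weight {total}")
    order = index.order[center]
    dists = index.sorted_dist[center]
    cum = np.cumsum(cohort.weights[order])
    j = int(np.searchsorted(cum, W, side="left"))
    j = min(j, cohort.n - 1)  # guard: W == total with float round-off
    radius = float(dists[j])
    j_end = int(np.searchsorted(dists, radius, side="right")) - 1
    return Sphere(
        center=center,
        members=order[: j_end + 1].copy(),
        radius=radius,
        cohort_weight=float(cum[j_end]),
        requested_weight=W,
    )


def sphere_table(sphere: Sphere, cohort: Cohort) -> ContingencyTable:
    """Phenotype-by-membership 2x2 table of a sphere.

    a = diseased weight inside, b = diseased weight outside, c = healthy
    weight inside, d = healthy weight outside; a+b+c+d equals the total
    cohort weight.
    """
    w = cohort.weights[sphere.members]
    dis = cohort.diseased[sphere.members]
    a = _seqsum(w * dis)
    c = _seqsum(w * ~dis)
    b = cohort.total_diseased_weight - a
    d = cohort.total_healthy_weight - c
    # clamp float round-off on exhaustive spheres
    return ContingencyTable(a, max(b, 0.0), c, max(d, 0.0))


def all_sphere_tables(
    W: float, cohort: Cohort, index: NeighborIndex | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sphere tables for every subject-centered sphere of weight ``W``.

    Returns per-center arrays ``(a, b, c, d, j_end)`` where ``j_end[i]`` is
    the index of the last member along center ``i``'s neighbor list. The
    cells are bitwise identical to ``sphere_table(sphere_at(i, W, ...))``:
    prefix sums of ``np.cumsum`` match sequential accumulation exactly.
    """
    if index is None:
        index = build_neighbor_index(cohort)
    total = cohort.total_weight
    if W > total:
        raise ValueError(f"requested sphere weight {W} exceeds total cohort weight {total}")
    n = cohort.n
    dis_f = cohort.diseased.astype(float)

    # Scan only the leading neighbor columns: spheres of weight W rarely
    # need more than ~W/min_weight members. Prefix sums of np.cumsum are
    # identical to a full-row scan, so capping columns cannot change any
    # cell; the cap doubles until every sphere and its distance-tie shell
    # fit within it.
    m = min(n, max(64, 2 * int(np.ceil(W))))
    while True:
        sub = index.order[:, :m]
        w_ord = np.take(cohort.weights, sub)
        cum_w = np.cumsum(w_ord, axis=1)
        if m < n and np.any(cum_w[:, -1] < W):
            m = min(n, 2 * m)
            continue
        dist = index.sorted_dist[:, :m]
        rows = np.arange(n)
        j = np.minimum(
            np.array([np.searchsorted(cum_w[i], W, side="left") for i in range(n)]),
            m - 1,
        )
        radius = dist[rows, j]
        j_end = np.array(
            [np.searchsorted(dist[i], radius[i], side="right") - 1 for i in range(n)]
        )
        # a distance tie at the cap boundary may continue past it
        if m < n and np.any(j_end >= m - 1):
            m = min(n, 2 * m)
            continue
        break
    wd = w_ord * np.take(dis_f, sub)
    wh = w_ord - wd  # exact: wd is either 0 or the full weight
    a = np.cumsum(wd, axis=1)[rows, j_end]
    c = np.cumsum(wh, axis=1)[rows, j_end]
    b = np.maximum(cohort.total_diseased_weight - a, 0.0)
    d = np.maximum(cohort.total_healthy_weight - c, 0.0)
    return a, b, c, d, j_end


def all_sphere_ors(
    W: float, cohort: Cohort, index: NeighborIndex | None = None
) -> np.ndarray:
    """Haldane-corrected sphere OR for every subject-centered sphere.

    Equivalent to ``odds_ratio(sphere_table(sphere_at(i, W, ...)),
    haldane=True)`` for every subject ``i``.
    """
    a, b, c, d, _ = all_sphere_tables(W, cohort, index)
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def single_sphere_or(center: int, W: float, cohort: Cohort, index: NeighborIndex | None = None) -> float:
    """Haldane sphere OR of one subject-centered sphere (reference path)."""
    return odds_ratio(sphere_table(sphere_at(center, W, cohort, index), cohort), haldane=True)
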