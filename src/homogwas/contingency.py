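"""Weighted 2x2 contingency tables, odds ratios and the Fisher exact test.

The 2x2 table crossing a binary phenotype (diseased/healthy) with a binary
genotype (A / ~A) is the basic object of case-control association testing.
When subjects carry fractional statistical weights the cells are nonnegative
reals; the Fisher exact test is then applied to the table rounded to the
nearest integer.

Cell layout (rows = phenotype, columns = genotype)::

            A     ~A
  diseased  a      b
  healthy   c      d

so that the odds ratio is OR = (a*d)/(b*c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "ContingencyTable",
    "odds_ratio",
    "extremeness",
    "round_table",
    "fisher_exact_p",
]

#: tolerance used to decide whether a float cell is (numerically) an integer
_INT_EPS = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 phenotype-by-genotype table with nonnegative real cells.

    Parameters
    ----------
    a, b, c, d : float
        Cell weights: ``a`` diseased & A, ``b`` diseased & ~A,
        ``c`` healthy & A, ``d`` healthy & ~A.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"cell {name!r} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[float, float]:
        """(diseased, healthy) totals."""
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[float, float]:
        """(A, ~A) totals."""
        return (self.a + self.c, self.b + self.d)

    def is_integral(self) -> bool:
        return all(
            abs(v - round(v)) <= _INT_EPS for v in (self.a, self.b, self.c, self.d)
        )

    def rounded(self) -> "ContingencyTable":
        """Round each cell to the nearest integer, halves away from zero."""
        return ContingencyTable(*(_round_half_away(v) for v in (self.a, self.b, self.c, self.d)))


def _round_half_away(x: float) -> float:
    # cells are nonnegative, so away-from-zero == upward at .5
    return math.floor(x + 0.5)


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Odds ratio (a*d)/(b*c) of a 2x2 table.

    With ``haldane=True`` the Anscombe-Haldane correction adds 0.5 to every
    cell, so the estimate is finite and positive even with empty cells.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    for name, v in (("b", b), ("c", c)):
        if v == 0:
            raise ValueError(
                f"odds ratio undefined: cell {name!r} is zero (use haldane=True)"
            )
    return (a * d) / (b * c)


def extremeness(or_value: float) -> float:
    """Distance of an odds ratio from unity, symmetric under inversion.

    OR = 3 and OR = 1/3 are equally extreme: ``max(OR, 1/OR)``.
    """
    if not (or_value > 0) or not math.isfinite(or_value):
        raise ValueError(f"odds ratio must be a positive finite number, got {or_value}")
    return max(or_value, 1.0 / or_value)


def round_table(table: ContingencyTable) -> ContingencyTable:
    """Round every cell to the nearest integer (halves away from zero)."""
    return table.rounded()


@lru_cache(maxsize=200_000)
def _fisher_int(a: int, b: int, c: int, d: int) -> float:
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0  # a zero margin carries no evidence either way
    p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1]
    return min(float(p), 1.0)


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of an integer 2x2 table.

    Uses the minimum-likelihood two-sided convention: the sum of
    hypergeometric probabilities of all tables with the same margins whose
    point probability does not exceed that of the observed table. Tables
    with a zero row or column margin return 1.0. Non-integer cells are a
    contract violation -- round the table first.
    """
    if not table.is_integral():
        raise ValueError(
            "fisher_exact_p requires integer cells; apply round_table first "
            f"(got {table})"
        )
    a, b, c, d = (int(round(v)) for v in (table.a, table.b, table.c, table.d))
    return _fisher_int(a, b, c, d)
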