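"""Reporting-quality trend statistics and reviewer-agreement measures.

The central question these support: is the fraction of cluster randomized
trials whose design is clearly flagged in the title or abstract rising
over calendar time?

Two trend tests are provided.

``method="proportions"`` (default) regresses the yearly proportions on the
year (unweighted ordinary least squares) and refers the slope z = b/SE(b)
to the standard normal.  This is the construction under which the
published headline figures for the gold-standard table reproduce to
printed precision; it weights each year equally, which damps the influence
of one heavily sampled year.

``method="cochran-armitage"`` is the classical Cochran–Armitage test with
equally spaced integer year scores, returned as a signed normal deviate.
It weights years by their trial counts and is the textbook choice when
sampling is even across years.

Both statistics are invariant to adding a constant to all year scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import GoldLabels, Identifiability


class TrendError(ValueError):
    pass


@dataclass(frozen=True)
class TrendRow:
    year: int
    identified: int
    total: int

    def __post_init__(self):
        if self.total < 0 or self.identified < 0 or self.identified > self.total:
            raise TrendError(
                f"year {self.year}: identified {self.identified} / total {self.total}"
            )

    @property
    def proportion(self) -> float:
        return self.identified / self.total


@dataclass(frozen=True)
class TrendTable:
    """Ordered (year, identified, total) rows, years strictly increasing."""

    rows: tuple[TrendRow, ...]

    def __post_init__(self):
        years = [r.year for r in self.rows]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise TrendError("years must be strictly increasing")

    @property
    def total_identified(self) -> int:
        return sum(r.identified for r in self.rows)

    @property
    def total(self) -> int:
        return sum(r.total for r in self.rows)

    @property
    def overall_proportion(self) -> float:
        return self.total_identified / self.total

    def exclude_years(self, years: Iterable[int]) -> "TrendTable":
        drop = set(years)
        return TrendTable(tuple(r for r in self.rows if r.year not in drop))

    def pool(self, years: Iterable[int]) -> tuple[int, int]:
        """(identified, total) summed over the given years."""
        keep = set(years)
        rows = [r for r in self.rows if r.year in keep]
        return sum(r.identified for r in rows), sum(r.total for r in rows)

    @staticmethod
    def from_counts(rows: Sequence[tuple[int, int, int]]) -> "TrendTable":
        return TrendTable(tuple(TrendRow(*r) for r in rows))


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float  # signed normal deviate; positive = rising proportion
    p_value: float  # two-sided, normal reference
    method: str


def trend_test(table: TrendTable, method: str = "proportions") -> TrendTestResult:
    """Test for a monotone trend in proportions across years.

    Requires at least two rows with positive totals.  See the module
    docstring for the two methods.
    """
    rows = [r for r in table.rows if r.total > 0]
    if len(rows) < 2:
        raise TrendError("need at least two rows with positive totals")
    years = np.array([r.year for r in rows], dtype=float)
    x = np.array([r.identified for r in rows], dtype=float)
    n = np.array([r.total for r in rows], dtype=float)

    if method == "proportions":
        p = x / n
        s = years - years.mean()
        sxx = float((s * s).sum())
        if sxx == 0:
            raise TrendError("all rows share one year")
        slope = float((s * p).sum()) / sxx
        resid = p - p.mean() - slope * s
        dof = len(rows) - 2
        if dof <= 0:
            raise TrendError("proportions method needs at least three rows")
        se = math.sqrt(float((resid**2).sum()) / dof / sxx)
        if se == 0:
            z = 0.0 if slope == 0 else math.copysign(math.inf, slope)
        else:
            z = slope / se
    elif method == "cochran-armitage":
        N = n.sum()
        pbar = x.sum() / N
        if pbar in (0.0, 1.0):
            raise TrendError("trend undefined: all outcomes identical")
        s = years - years.mean()
        t = float((x * s).sum()) - pbar * float((n * s).sum())
        var = pbar * (1 - pbar) * (float((n * s * s).sum()) - float((n * s).sum()) ** 2 / N)
        z = t / math.sqrt(var)
    else:
        raise TrendError(f"unknown method {method!r}")

    p_two = float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return TrendTestResult(statistic=float(z), p_value=p_two, method=method)


@dataclass(frozen=True)
class ProportionDiffCI:
    """Difference of two proportions, in percentage points."""

    difference: float
    lower: float
    upper: float
    confidence: float


def diff_proportions_ci(
    x1: int, n1: int, x2: int, n2: int, confidence: float = 0.95
) -> ProportionDiffCI:
    """Wald interval for p2 - p1, no continuity correction.

    (p2-p1) ± z·sqrt(p1(1-p1)/n1 + p2(1-p2)/n2), z the normal quantile at
    the stated confidence (1.959964 at 95%).  Returned in percentage
    points.
    """
    if n1 <= 0 or n2 <= 0:
        raise TrendError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise TrendError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    z = float(stats.norm.ppf(0.5 + confidence / 2))
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    diff = p2 - p1
    return ProportionDiffCI(
        difference=100 * diff,
        lower=100 * (diff - z * se),
        upper=100 * (diff + z * se),
        confidence=confidence,
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    lower: float | None
    upper: float | None


def cohen_kappa(agreement: Sequence[Sequence[int]], confidence: float = 0.95) -> KappaResult:
    """Cohen's kappa for a 2x2 (or k x k) inter-rater inclusion table.

    kappa = (po - pe) / (1 - pe) with the asymptotic large-sample standard
    error sqrt(po(1-po)/(n(1-pe)^2)); the CI is kappa ± z·SE, clipped to
    [-1, 1].  Chance-perfect marginals (pe = 1) yield an undefined marker.
    """
    m = np.asarray(agreement, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise TrendError("agreement table must be square")
    if (m < 0).any():
        raise TrendError("agreement cells must be non-negative")
    n = m.sum()
    if n <= 0:
        raise TrendError("agreement table is empty")
    po = np.trace(m) / n
    row = m.sum(axis=1) / n
    col = m.sum(axis=0) / n
    pe = float((row * col).sum())
    if pe >= 1.0:
        return KappaResult(None, None, None)
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    z = float(stats.norm.ppf(0.5 + confidence / 2))
    return KappaResult(
        kappa=float(kappa),
        lower=float(max(-1.0, kappa - z * se)),
        upper=float(min(1.0, kappa + z * se)),
    )


def aggregate_trend(
    labels: GoldLabels, predicate: Identifiability = Identifiability.CLEAR
) -> TrendTable:
    """Per-year counts of CRTs in the given class over all CRTs.

    Each row: (year, CRTs in class, all CRTs that year).  CRTs without a
    usable year would be excluded with a warning, but label records always
    carry one, so the table covers every CRT in *labels*.
    """
    per_year: dict[int, list[int]] = {}
    for _, rec in labels.items():
        if not rec.is_crt:
            continue
        cell = per_year.setdefault(rec.year, [0, 0])
        cell[1] += 1
        if rec.identifiability is predicate:
            cell[0] += 1
    if not per_year:
        raise TrendError("labels contain no CRTs")
    rows = tuple(
        TrendRow(year, ident, total)
        for year, (ident, total) in sorted(per_year.items())
    )
    return TrendTable(rows)
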