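"""Retrieval accuracy metrics for search filters.

All metrics derive from the 2x2 contingency of retrieval against the gold
standard: ``a`` eligible retrieved, ``b`` ineligible retrieved, ``c``
eligible missed, ``d`` ineligible missed, ``N = a+b+c+d``.

* sensitivity (recall) = a / (a + c)
* fall-out (1 - specificity) = b / (b + d)
* precision = a / (a + b)
* number needed to read (NNR) = (a + b) / a, the reciprocal of precision

A metric whose denominator (or numerator, for NNR) is zero is carried as
an explicit ``None``, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # eligible, retrieved
    b: int  # ineligible, retrieved
    c: int  # eligible, not retrieved
    d: int  # ineligible, not retrieved

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise MetricsError(f"cell {name} is negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def retrieved(self) -> int:
        return self.a + self.b

    @property
    def eligible(self) -> int:
        return self.a + self.c


def make_contingency(
    retrieved: set[str], relevant: set[str], corpus_size: int
) -> ContingencyTable:
    """Cross-tabulate a retrieved uid set against the relevant uid set.

    ``corpus_size`` is the total number of articles examined (N); a
    negative implied d cell is an input inconsistency.
    """
    a = len(retrieved & relevant)
    b = len(retrieved - relevant)
    c = len(relevant - retrieved)
    d = corpus_size - a - b - c
    if d < 0:
        raise MetricsError(
            f"corpus_size {corpus_size} smaller than |retrieved ∪ relevant| = {a+b+c}"
        )
    return ContingencyTable(a, b, c, d)


@dataclass(frozen=True)
class MetricsReport:
    """Proportions in [0, 1]; percentage accessors round to 1 d.p.

    ``nnr`` is computed from the raw counts, (a+b)/a.
    ``nnr_from_rounded_precision`` is the display variant 1/(precision
    rounded to one decimal percentage point): published tables sometimes
    quote that form (e.g. 28.6 = 1/3.5% where the raw counts give 28.5).
    """

    table: ContingencyTable
    sensitivity: float | None
    one_minus_specificity: float | None
    precision: float | None
    nnr: float | None

    @property
    def nnr_from_rounded_precision(self) -> float | None:
        if self.precision is None or self.precision == 0:
            return None
        return 100.0 / round(self.precision * 100.0, 1)

    @staticmethod
    def _pct(x: float | None) -> float | None:
        return None if x is None else round(100.0 * x, 1)

    @property
    def sensitivity_pct(self) -> float | None:
        return self._pct(self.sensitivity)

    @property
    def one_minus_specificity_pct(self) -> float | None:
        return self._pct(self.one_minus_specificity)

    @property
    def precision_pct(self) -> float | None:
        return self._pct(self.precision)

    def as_dict(self) -> dict:
        t = self.table
        return {
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "N": t.N,
            "retrieved": t.retrieved,
            "sensitivity": self.sensitivity,
            "one_minus_specificity": self.one_minus_specificity,
            "precision": self.precision,
            "nnr": self.nnr,
        }


def compute_metrics(t: ContingencyTable) -> MetricsReport:
    sens = t.a / (t.a + t.c) if (t.a + t.c) > 0 else None
    fallout = t.b / (t.b + t.d) if (t.b + t.d) > 0 else None
    prec = t.a / (t.a + t.b) if (t.a + t.b) > 0 else None
    nnr = (t.a + t.b) / t.a if t.a > 0 else None
    return MetricsReport(
        table=t,
        sensitivity=sens,
        one_minus_specificity=fallout,
        precision=prec,
        nnr=nnr,
    )


@dataclass(frozen=True)
class RelativeRecall:
    hits: int
    reference_size: int

    @property
    def recall(self) -> float:
        return self.hits / self.reference_size

    @property
    def recall_pct(self) -> float:
        return round(100.0 * self.recall, 1)


def relative_recall(retrieved: set[str], reference_trials: set[str]) -> RelativeRecall:
    """Fraction of an independent reference trial set that was retrieved."""
    if not reference_trials:
        raise MetricsError("reference trial set is empty")
    return RelativeRecall(
        hits=len(retrieved & reference_trials),
        reference_size=len(reference_trials),
    )


@dataclass(frozen=True)
class WorkloadParams:
    """Screening-workload assumptions.

    ``target_crt_count``: how many relevant trials the review needs.
    ``minutes_per_article``: screening time per retrieved citation.
    """

    target_crt_count: int
    minutes_per_article: float

    def __post_init__(self):
        if self.target_crt_count <= 0 or self.minutes_per_article <= 0:
            raise MetricsError("workload parameters must be positive")


def workload_hours(metrics: MetricsReport, params: WorkloadParams) -> float:
    """Screening hours to reach the target: target × NNR × minutes / 60.

    NNR comes from the raw counts (a+b)/a.  Undefined or zero precision is
    an error — with no true positives no screening volume reaches the
    target.
    """
    if metrics.nnr is None or metrics.precision in (None, 0):
        raise MetricsError("workload undefined: precision is zero or undefined")
    return params.target_crt_count * metrics.nnr * params.minutes_per_article / 60.0
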