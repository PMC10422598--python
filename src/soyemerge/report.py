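"""Emergence proportions, uniformity verdicts and count-evaluation statistics.

The emergence proportion of stage i is ``EP_i = TP_i / ST`` where ``TP_i`` is
the number of seedlings detected at stage i (VE, VC, V1) and ``ST`` the total
emerged. Predicted counts are evaluated against manual counts per monitoring
site with R^2, RMSE, MAE and a mean per-site relative accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StageCounts",
    "EmergenceReport",
    "UniformityRules",
    "CountComparison",
    "CountMetrics",
    "emergence_proportion",
    "proportion_error",
    "proportion_error_table",
    "uniformity_verdict",
    "count_metrics",
]

STAGES = ("VE", "VC", "V1")


@dataclass
class StageCounts:
    """Per-stage emerged-seedling counts; ``total`` is their sum."""

    ve: int
    vc: int
    v1: int

    def __post_init__(self) -> None:
        if min(self.ve, self.vc, self.v1) < 0:
            raise ValueError("stage counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ve + self.vc + self.v1

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.ve, self.vc, self.v1)


@dataclass
class EmergenceReport:
    ep: Optional[tuple[float, float, float]]  # None for an empty field
    counts: StageCounts
    date: Optional[str] = None
    uniformity: Optional["UniformityVerdict"] = None

    @property
    def empty_field(self) -> bool:
        return self.ep is None


@dataclass
class UniformityRules:
    """Thresholds codifying the qualitative notion of emergence uniformity.

    A stand is uniform when one stage dominates (proportion >= theta_dom).
    It is non-uniform when all three stages coexist substantially (each
    >= theta_coexist) or when the emerged total falls below a fraction
    theta_density of the expected plant count.
    """

    theta_dom: float = 0.90
    theta_coexist: float = 0.05
    theta_density: float = 0.5
    expected_total: Optional[int] = None


@dataclass
class UniformityVerdict:
    uniform: bool
    reasons: list[str]


def emergence_proportion(counts: StageCounts, date: Optional[str] = None) -> EmergenceReport:
    """EP_i = TP_i / ST per stage; the triple sums to 1 whenever ST > 0."""
    st = counts.total
    if st == 0:
        return EmergenceReport(ep=None, counts=counts, date=date)
    ep = tuple(c / st for c in counts.as_tuple())
    return EmergenceReport(ep=ep, counts=counts, date=date)


def proportion_error(predicted: Sequence[float], real: Sequence[float]) -> tuple[float, ...]:
    """Per-stage absolute error |predicted_i - real_i|."""
    if len(predicted) != len(real):
        raise ValueError("proportion triples must have equal length")
    return tuple(abs(p - r) for p, r in zip(predicted, real))


def proportion_error_table(rows: Sequence[tuple[Sequence[float], Sequence[float]]]
                           ) -> tuple[list[tuple[float, ...]], float, float]:
    """Errors for many (predicted, real) pairs plus the table-wide max and min."""
    errors = [proportion_error(p, r) for p, r in rows]
    flat = [e for row in errors for e in row]
    return errors, max(flat), min(flat)


def uniformity_verdict(report: EmergenceReport,
                       rules: UniformityRules | None = None) -> UniformityVerdict:
    """Apply the configured uniformity rules; non-uniform reasons are listed."""
    rules = rules or UniformityRules()
    reasons: list[str] = []
    if report.empty_field:
        return UniformityVerdict(uniform=False, reasons=["no emerged seedlings"])
    ep = report.ep
    if all(p >= rules.theta_coexist for p in ep):
        reasons.append("multi-stage coexistence")
    if rules.expected_total is not None and \
            report.counts.total < rules.theta_density * rules.expected_total:
        reasons.append("low emergence")
    if not reasons and max(ep) < rules.theta_dom:
        reasons.append("no dominant stage")
    return UniformityVerdict(uniform=not reasons, reasons=reasons)


@dataclass
class CountComparison:
    """Real vs predicted seedling counts over monitoring sites."""

    real: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.real.shape != self.predicted.shape or self.real.ndim != 1:
            raise ValueError("real and predicted must be 1-D and the same length")
        if (self.real < 0).any() or (self.predicted < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.real)


@dataclass
class CountMetrics:
    r2: Optional[float]
    rmse: float
    mae: float
    average_accuracy_pct: float
    n_excluded_zero_truth: int = 0


def count_metrics(cmp: CountComparison) -> CountMetrics:
    """R^2, RMSE, MAE and mean per-site relative accuracy.

    R^2 is the standard coefficient of determination
    ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``; it is None (flagged
    undefined) when the real counts have zero variance. Average accuracy is
    ``mean over sites of (1 - |yhat - y| / y) * 100``, with zero-truth sites
    excluded from the mean and counted separately.
    """
    y, yhat = cmp.real, cmp.predicted
    if cmp.n < 2:
        raise ValueError("need at least 2 sites")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum(resid ** 2) / ss_tot)
    nonzero = y > 0
    n_excluded = int((~nonzero).sum())
    if nonzero.any():
        acc = float(np.mean((1.0 - np.abs(resid[nonzero]) / y[nonzero])) * 100.0)
    else:
        acc = float("nan")
    return CountMetrics(r2=r2, rmse=rmse, mae=mae, average_accuracy_pct=acc,
                        n_excluded_zero_truth=n_excluded)
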