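"""Prevalence estimates and 2x2 diagnostic accuracy with binomial CIs.

Proportions keep full precision internally; display rounding is half-up to
one decimal, matching how clinical prevalence tables are conventionally
printed.  Confidence intervals use the Wilson score method by default
(Wald available), through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "round_half_up",
    "ProportionEstimate",
    "prevalence",
    "ConfusionTable",
    "confusion",
    "accuracy_stats",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3 at one digit), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionEstimate:
    """numerator/denominator as a percent with a 95% binomial CI (percent)."""

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float
    ci_method: str = "wilson"

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.percent, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )

    def display(self, ndigits: int = 1) -> str:
        p, lo, hi = self.rounded(ndigits)
        return f"{p:.{ndigits}f} ({lo:.{ndigits}f}-{hi:.{ndigits}f})"

    @property
    def proportion(self) -> float:
        return self.percent / 100.0


def prevalence(
    numerator: int,
    denominator: int,
    *,
    ci_method: str = "wilson",
    alpha: float = 0.05,
) -> ProportionEstimate:
    """Binomial proportion as percent with a 95% (by default) CI.

    ``ci_method`` is "wilson" (score interval, default) or "wald" (normal
    approximation).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    method = {"wilson": "wilson", "wald": "normal"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method=method)
    p = numerator / denominator
    lo, hi = max(0.0, min(float(lo), p)), min(1.0, max(float(hi), p))
    return ProportionEstimate(
        numerator=int(numerator),
        denominator=int(denominator),
        percent=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        ci_method=ci_method,
    )


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a predicted set against a reference set over a universe."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_positive: set, ref_positive: set, universe: set) -> ConfusionTable:
    """Cross-tabulate predicted vs reference membership over ``universe``."""
    if not pred_positive <= universe:
        raise ValueError("predicted positives must be a subset of the universe")
    if not ref_positive <= universe:
        raise ValueError("reference positives must be a subset of the universe")
    tp = len(pred_positive & ref_positive)
    fp = len(pred_positive - ref_positive)
    fn = len(ref_positive - pred_positive)
    tn = len(universe) - tp - fp - fn
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_stats(
    table: ConfusionTable,
    *,
    ci_method: str = "wilson",
    alpha: float = 0.05,
) -> dict[str, Optional[ProportionEstimate]]:
    """Sensitivity, specificity, PPV and NPV with binomial CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    def est(num: int, den: int) -> Optional[ProportionEstimate]:
        if den == 0:
            return None
        return prevalence(num, den, ci_method=ci_method, alpha=alpha)

    return {
        "sensitivity": est(table.tp, table.tp + table.fn),
        "specificity": est(table.tn, table.tn + table.fp),
        "ppv": est(table.tp, table.tp + table.fp),
        "npv": est(table.tn, table.tn + table.fn),
    }
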