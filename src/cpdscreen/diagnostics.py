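"""Diagnostic-accuracy statistics for a screening rule.

Builds 2x2 confusion counts from truth/prediction label pairs and computes
sensitivity, specificity, positive and negative predictive value with 95%
confidence intervals.  The default interval is the continuity-corrected
Wilson score interval (Newcombe's form, as used by the common clinical
test-evaluation calculators); plain Wilson and Clopper-Pearson exact
intervals are available by flag.

Point estimates are exact integer ratios.  A statistic whose denominator is
zero is reported as undefined (None), never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

CI_METHODS = ("wilson_cc", "wilson", "clopper_pearson")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts of a binary screen against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    truth: Sequence, predicted: Sequence, positive_class
) -> ConfusionCounts:
    """Count TP/FP/FN/TN of predictions against truth labels."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_cc_interval(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Newcombe's closed form; bounds are clamped to [0, 1], with the lower
    bound exactly 0 when successes = 0 and the upper exactly 1 when
    successes = n.
    """
    if n < 1 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts: {successes}/{n}")
    z = stats.norm.ppf(0.5 + level / 2)
    p = successes / n
    q = 1 - p
    if successes == 0:
        lower = 0.0
    else:
        lower = (
            2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))
        ) / (2 * (n + z * z))
    if successes == n:
        upper = 1.0
    else:
        upper = (
            2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))
        ) / (2 * (n + z * z))
    return (float(max(0.0, lower)), float(min(1.0, upper)))


def proportion_interval(
    successes: int, n: int, method: str = "wilson_cc", level: float = 0.95
) -> tuple[float, float]:
    """Binomial proportion CI by the requested method."""
    if method == "wilson_cc":
        return wilson_cc_interval(successes, n, level)
    if method == "wilson":
        lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
        return (float(lo), float(hi))
    if method == "clopper_pearson":
        lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}; choose from {CI_METHODS}")


@dataclass(frozen=True)
class AccuracyStats:
    """Clinical accuracy of a binary screen, with 95% CIs.

    Each statistic is an exact ratio in [0, 1] or None when its denominator
    is zero; the matching CI is None in that case.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    ci_method: str = "wilson_cc"

    def as_dict(self, percent: bool = True, ndigits: int = 2) -> dict:
        """Report-ready dict: percentages at 2 decimals, CIs as proportions."""
        out: dict = {"counts": vars(self.counts), "ci_method": self.ci_method}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            val = getattr(self, name)
            ci = getattr(self, f"{name}_ci")
            if val is None:
                out[name] = None
                out[f"{name}_ci"] = None
            else:
                out[name] = round(val * 100, ndigits) if percent else round(val, 4)
                out[f"{name}_ci"] = [round(float(ci[0]), ndigits), round(float(ci[1]), ndigits)]
        return out


def accuracy_stats(
    counts: ConfusionCounts, ci_method: str = "wilson_cc", level: float = 0.95
) -> AccuracyStats:
    """Sensitivity, specificity, PPV and NPV with confidence intervals.

    sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN).
    """
    def ratio_ci(num: int, den: int):
        if den == 0:
            return None, None
        return num / den, proportion_interval(num, den, ci_method, level)

    sens, sens_ci = ratio_ci(counts.tp, counts.tp + counts.fn)
    spec, spec_ci = ratio_ci(counts.tn, counts.tn + counts.fp)
    ppv, ppv_ci = ratio_ci(counts.tp, counts.tp + counts.fp)
    npv, npv_ci = ratio_ci(counts.tn, counts.tn + counts.fn)
    return AccuracyStats(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        ci_method=ci_method,
    )
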