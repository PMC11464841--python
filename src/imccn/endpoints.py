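"""Trial endpoint statistics: exact binomial intervals, KM, sample size.

Objective response rate (ORR = CR + PR) and disease control rate (DCR = CR +
PR + SD) carry exact Clopper-Pearson confidence intervals obtained from Beta
quantiles. Survival uses the Kaplan-Meier product-limit estimator with the
median read as the earliest time at which S(t) <= 0.5. The one-proportion
sample size uses the unpooled normal-approximation formula

    n = ceil( (z_{1-a/2} sqrt(p0 q0) + z_{power} sqrt(p1 q1))^2 / (p1-p0)^2 )

with an exact-binomial power search available as a cross-check mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


@dataclass(frozen=True)
class ExactInterval:
    """A proportion with its exact (Clopper-Pearson) confidence bounds."""

    estimate: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.estimate <= self.upper <= 1:
            raise ValidationError(
                f"interval ordering violated: {self.lower}, {self.estimate}, "
                f"{self.upper}")

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (round(100 * self.estimate, ndigits),
                round(100 * self.lower, ndigits),
                round(100 * self.upper, ndigits))


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> ExactInterval:
    """Exact binomial confidence interval via Beta-distribution quantiles.

    The lower bound is 0 when ``successes = 0`` and the upper bound is 1 when
    ``successes = n`` (boundary conventions of the exact method).
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValidationError("confidence level must lie in (0, 1)")
    alpha = 1 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return ExactInterval(successes / n, lower, upper, level)


def summarize_response(table: pd.DataFrame, analysis_set: str | None = None,
                       level: float = 0.95) -> dict:
    """Counts by best-response category plus ORR and DCR with exact CIs.

    ``analysis_set`` names a boolean flag column (e.g. ``'fas'``) used to
    subset the table; ``None`` uses every row.
    """
    sub = table[table[analysis_set].astype(bool)] if analysis_set else table
    if len(sub) == 0:
        raise ValidationError("analysis set is empty")
    n = len(sub)
    counts = {c: int((sub["best_response"] == c).sum())
              for c in RESPONSE_CATEGORIES}
    responders = counts["CR"] + counts["PR"]
    controlled = responders + counts["SD"]
    if responders == 0 and counts["NE"] == n:
        warnings.warn("all patients non-evaluable; ORR is 0")
    return {
        "n": n,
        "counts": counts,
        "orr": clopper_pearson(responders, n, level),
        "dcr": clopper_pearson(controlled, n, level),
    }


@dataclass
class KaplanMeierResult:
    """Product-limit curve with the declared median convention."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float | None          # None = not reached

    def rate_at(self, t: float) -> float:
        """Survival probability at horizon ``t`` (step-function read-off)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(times, events) -> KaplanMeierResult:
    """Kaplan-Meier estimate; median = earliest t with S(t) <= 0.5."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValidationError("times and events must be aligned")
    if times.size == 0:
        raise ValidationError("no observations")
    if times.min() < 0:
        raise ValidationError("times must be nonnegative")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    below = np.flatnonzero(survival <= 0.5)
    median = float(timeline[below[0]]) if below.size else None
    return KaplanMeierResult(timeline=timeline, survival=survival, median=median)


@dataclass(frozen=True)
class SampleSizeSpec:
    """One-proportion design: null p0, alternative p1, two-sided alpha,
    power, and the anticipated dropout rate."""

    p0: float
    p1: float
    alpha: float = 0.05
    power: float = 0.80
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1):
            raise ValidationError("p0 and p1 must lie in (0, 1)")
        if self.p0 == self.p1:
            raise ValidationError("p0 = p1 gives an infinite sample size")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValidationError("alpha and power must lie in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")


def one_prop_sample_size(p0: float, p1: float, alpha: float = 0.05,
                         power: float = 0.80, method: str = "normal") -> int:
    """Required n for a two-sided one-proportion test.

    ``method='normal'`` evaluates the unpooled normal-approximation formula;
    ``method='exact'`` searches for the smallest n whose exact binomial test
    at level alpha reaches the target power (cross-check mode; exact designs
    are typically a little larger).
    """
    SampleSizeSpec(p0, p1, alpha, power)  # validation
    if method == "normal":
        z_a = stats.norm.ppf(1 - alpha / 2)
        z_b = stats.norm.ppf(power)
        num = z_a * math.sqrt(p0 * (1 - p0)) + z_b * math.sqrt(p1 * (1 - p1))
        return math.ceil((num / (p1 - p0)) ** 2)
    if method == "exact":
        lo, hi = (p0, p1) if p1 > p0 else (p1, p0)
        for n in range(1, 10001):
            if p1 > p0:
                # smallest critical count with upper-tail size <= alpha/2
                c = int(stats.binom.isf(alpha / 2, n, p0)) + 1
                achieved = float(stats.binom.sf(c - 1, n, p1))
            else:
                c = int(stats.binom.ppf(alpha / 2, n, p0)) - 1
                achieved = float(stats.binom.cdf(c, n, p1))
            if achieved >= power:
                return n
        raise ValidationError("no n <= 10000 reaches the requested power")
    raise ValidationError(f"unknown method {method!r}")


def inflate_for_dropout(n: int, dropout: float) -> int:
    """Enrollment target accounting for dropout: ceil(n / (1 - dropout))."""
    if not 0 <= dropout < 1:
        raise ValidationError("dropout must lie in [0, 1)")
    return math.ceil(n / (1 - dropout))


def endpoint_report(table: pd.DataFrame, analysis_set: str | None = "fas",
                    level: float = 0.95) -> dict:
    """JSON-ready endpoint summary: response rates plus KM medians."""
    summary = summarize_response(table, analysis_set, level)
    sub = table[table[analysis_set].astype(bool)] if analysis_set else table
    report = {
        "n": summary["n"],
        "counts": summary["counts"],
        "orr_percent": summary["orr"].as_percent(),
        "dcr_percent": summary["dcr"].as_percent(),
        "confidence_level": level,
    }
    if {"pfs_months", "pfs_event"} <= set(sub.columns):
        km = km_estimator(sub["pfs_months"], sub["pfs_event"])
        report["median_pfs_months"] = km.median
    if {"os_months", "os_event"} <= set(sub.columns):
        km = km_estimator(sub["os_months"], sub["os_event"])
        report["median_os_months"] = km.median
        report["os_rate_12mo"] = km.rate_at(12.0)
    return report
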