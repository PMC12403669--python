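"""Mutation-rate estimation with exact Poisson intervals and rate comparison.

The per-class mutation rate of an MA experiment is the pooled event
count divided by the exposure denominator

    g = sum over lines of (callable sites x total cell divisions),

in units of per nucleotide site per cell division.  Counts are treated
as Poisson; confidence intervals are the exact (Garwood) chi-square
quantile bounds, which are conservative (coverage >= nominal).  Two
groups are compared by the rate ratio with a Wald interval on the log
scale and by the exact conditional binomial test (conditioning on the
total count makes one count binomial with success probability
proportional to its exposure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from scipy import stats

from .records import ExperimentGroup

__all__ = [
    "ExposureDenominator",
    "RateEstimate",
    "RateComparison",
    "exposure",
    "garwood_ci",
    "estimate_rate",
    "rate_ratio_test",
]


@dataclass(frozen=True)
class ExposureDenominator:
    """Total mutational opportunity of a group (site x division x line).

    ``approximate`` marks values built from group means (the fallback
    when per-line callable sites are unavailable) rather than the
    exact per-line sum.
    """

    group: str
    value: float
    n_lines: int
    mean_divisions: float
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("exposure must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """A per-site per-division rate with its exact Poisson interval."""

    mclass: str
    count: int
    exposure: ExposureDenominator
    mu: float
    ci_low: float
    ci_high: float
    conf_level: float


@dataclass(frozen=True)
class RateComparison:
    """Treatment/control rate ratio with Wald and exact conditional tests."""

    rr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_exact: float
    conf_level: float
    one_sided_flag: bool = False  # set when a zero count forces a one-sided CI


def exposure(
    group: ExperimentGroup, mean_sites: Optional[float] = None
) -> ExposureDenominator:
    """Exposure denominator g of a group.

    Uses the exact per-line sum of callable_sites x total_divisions.
    When some line lacks callable sites, falls back to
    n_lines x mean_sites x mean_divisions (``mean_sites`` must then be
    given) and flags the result as approximate.
    """
    if not group.lines:
        raise ValueError(f"group {group.name}: no lines")
    divisions = [ln.total_divisions for ln in group.lines]
    mean_div = sum(divisions) / len(divisions)
    if all(ln.callable_sites is not None for ln in group.lines):
        value = sum(ln.callable_sites * ln.total_divisions for ln in group.lines)
        return ExposureDenominator(group.name, value, group.n_lines, mean_div)
    if mean_sites is None:
        missing = [ln.line_id for ln in group.lines if ln.callable_sites is None]
        raise ValueError(
            f"group {group.name}: lines {missing} lack callable_sites and "
            "no mean_sites fallback was given"
        )
    value = group.n_lines * mean_sites * mean_div
    return ExposureDenominator(group.name, value, group.n_lines, mean_div,
                               approximate=True)


def garwood_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval, in event units.

    lower = chi2.ppf(alpha/2, 2k) / 2   (0 when k = 0)
    upper = chi2.ppf(1 - alpha/2, 2k + 2) / 2

    Divide by an exposure to obtain rate units.  The interval is
    conservative: coverage is at least the nominal level for every
    true mean.
    """
    if count < 0 or count != int(count):
        raise ValueError(f"count must be a non-negative integer, got {count}")
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    alpha = 1 - conf
    low = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return low, high


def estimate_rate(
    count: int,
    exposure: Union[ExposureDenominator, float],
    conf: float = 0.95,
    mclass: str = "BPS",
) -> RateEstimate:
    """Point estimate count/g with the Garwood interval scaled by g."""
    if isinstance(exposure, (int, float)):
        if exposure <= 0:
            raise ValueError("exposure must be positive")
        exposure = ExposureDenominator("", float(exposure), 0, float("nan"),
                                       approximate=True)
    g = exposure.value
    low, high = garwood_ci(count, conf)
    return RateEstimate(
        mclass=mclass,
        count=count,
        exposure=exposure,
        mu=count / g,
        ci_low=low / g,
        ci_high=high / g,
        conf_level=conf,
    )


def rate_ratio_test(
    x1: int, g1: float, x2: int, g2: float, conf: float = 0.95
) -> RateComparison:
    """Compare two Poisson rates: ratio (x2/g2)/(x1/g1), Wald CI, both p-values.

    ``p_wald`` comes from the z statistic ln(rr)/sqrt(1/x1 + 1/x2);
    ``p_exact`` is the two-sided exact binomial test of x2 successes in
    x1 + x2 trials against p0 = g2/(g1 + g2).  With x1 = 0 and x2 > 0
    the ratio is +inf and only the lower Wald bound is defined
    (``one_sided_flag`` set).
    """
    if g1 <= 0 or g2 <= 0:
        raise ValueError("exposures must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    n = x1 + x2
    if n == 0:
        raise ValueError("rate ratio undefined with both counts zero")
    p0 = g2 / (g1 + g2)
    p_exact = min(1.0, stats.binomtest(x2, n, p0).pvalue)
    if x1 == 0:
        return RateComparison(
            rr=math.inf, ci_low=math.nan, ci_high=math.inf,
            p_wald=math.nan, p_exact=p_exact, conf_level=conf,
            one_sided_flag=True,
        )
    if x2 == 0:
        return RateComparison(
            rr=0.0, ci_low=0.0, ci_high=math.nan,
            p_wald=math.nan, p_exact=p_exact, conf_level=conf,
            one_sided_flag=True,
        )
    rr = (x2 / g2) / (x1 / g1)
    se = math.sqrt(1 / x1 + 1 / x2)
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    ci_low = math.exp(math.log(rr) - z * se)
    ci_high = math.exp(math.log(rr) + z * se)
    p_wald = 2 * stats.norm.sf(abs(math.log(rr)) / se)
    return RateComparison(
        rr=rr, ci_low=ci_low, ci_high=ci_high,
        p_wald=min(1.0, p_wald), p_exact=p_exact, conf_level=conf,
    )
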