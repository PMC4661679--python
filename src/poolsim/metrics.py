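"""Replicate-level Monte-Carlo summaries: power, FPR, bias, % mean change.

Conventions mirrored throughout:

* Power counts replicates whose exposure-1 odds ratio is <= 0.1, >= 10, or
  Wald-significant at ``alpha``; the denominator is the *total* number of
  replicates (unstable ones included).  Extreme odds ratios count because a
  data analyst confronted with such a fit would have no doubt an association
  is present.
* The false positive rate (FPR) applies the same rule to the non-causal
  exposure 2.
* Bias is the mean, over stable replicates only, of the ratio of the
  replicate odds ratio to the population-truth odds ratio (1.0 = unbiased).
* The percent mean change compares pooled and individual analyses of the
  same replicate cohorts: ``100 * sum((pooled - individual)/pooled) / N``
  where the sum runs over replicates with a pooled OR strictly inside
  (0.1, 10) but ``N`` is the total replicate count, as the summary is
  conventionally printed.

Replicates whose fit raised an error are carried as ``None`` entries: they
count in every denominator, are never flagged in a numerator, and are
excluded from bias (they cannot be stable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .estimation import FitResult


@dataclass
class ScenarioSummary:
    """Aggregated performance of one simulation scenario."""

    power_pct: float
    fpr_pct: float
    bias_or1: float
    mean_or2: float
    pct_change_or1: float
    pct_change_or2: float
    n_stable: int
    n_replicates: int
    or1_population: float
    or2_population: float
    alpha: float = 0.05


def _flagged(fits, which: int, alpha: float) -> np.ndarray:
    out = np.zeros(len(fits), dtype=bool)
    for i, f in enumerate(fits):
        if f is None:
            continue
        orv = f.or1 if which == 1 else f.or2
        pv = f.p1 if which == 1 else f.p2
        if np.isfinite(orv) and (orv <= 0.1 or orv >= 10.0):
            out[i] = True
        elif np.isfinite(pv) and pv < alpha:
            out[i] = True
    return out


def power(fits: list[FitResult | None], alpha: float = 0.05) -> float:
    """Percent of replicates flagging exposure 1 (extreme OR or significant)."""
    if len(fits) == 0:
        raise UndefinedMetricError("power undefined with no replicates")
    return 100.0 * _flagged(fits, 1, alpha).mean()


def fpr(fits: list[FitResult | None], alpha: float = 0.05) -> float:
    """Percent of replicates flagging the non-causal exposure 2."""
    if len(fits) == 0:
        raise UndefinedMetricError("FPR undefined with no replicates")
    return 100.0 * _flagged(fits, 2, alpha).mean()


def _stable(fits):
    return [f for f in fits if f is not None and f.stable]


def bias(fits: list[FitResult | None], or_population: float, which: int = 1) -> float:
    """Mean ratio of stable-replicate OR to the population-truth OR."""
    if or_population <= 0 or not np.isfinite(or_population):
        raise UndefinedMetricError(f"population OR must be > 0, got {or_population}")
    stable = _stable(fits)
    if not stable:
        raise UndefinedMetricError("bias undefined with zero stable replicates")
    ors = np.array([f.or1 if which == 1 else f.or2 for f in stable])
    return float(np.mean(ors / or_population))


def mean_or(fits: list[FitResult | None], which: int = 2) -> float:
    """Mean odds ratio over stable replicates (reported for exposure 2)."""
    stable = _stable(fits)
    if not stable:
        raise UndefinedMetricError("mean OR undefined with zero stable replicates")
    return float(np.mean([f.or1 if which == 1 else f.or2 for f in stable]))


def pct_mean_change(
    pooled_fits: list[FitResult | None],
    individual_fits: list[FitResult | None],
    which: int = 1,
) -> float:
    """Percent mean difference between paired pooled and individual ORs.

    Pairs qualify when the pooled OR is strictly inside (0.1, 10); the
    divisor is the total number of replicate pairs.
    """
    if len(pooled_fits) != len(individual_fits) or len(pooled_fits) == 0:
        raise UndefinedMetricError("need equal, non-empty paired replicate lists")
    total = 0.0
    for fp, fi in zip(pooled_fits, individual_fits):
        if fp is None or fi is None:
            continue
        orp = fp.or1 if which == 1 else fp.or2
        ori = fi.or1 if which == 1 else fi.or2
        if np.isfinite(orp) and np.isfinite(ori) and 0.1 < orp < 10.0:
            total += (orp - ori) / orp
    return 100.0 * total / len(pooled_fits)


def summarize(
    fits: list[FitResult | None],
    population_fit: FitResult,
    alpha: float = 0.05,
    individual_fits: list[FitResult | None] | None = None,
) -> ScenarioSummary:
    """Roll one scenario's replicate fits into a :class:`ScenarioSummary`.

    ``individual_fits``, when given, are the paired individual-level analyses
    of the same cohorts and feed the percent-mean-change columns; otherwise
    those columns are NaN.
    """
    n_stable = len(_stable(fits))
    try:
        bias_val = bias(fits, population_fit.or1, which=1)
    except UndefinedMetricError:
        bias_val = np.nan
    try:
        mean2 = mean_or(fits, which=2)
    except UndefinedMetricError:
        mean2 = np.nan
    if individual_fits is not None:
        pc1 = pct_mean_change(fits, individual_fits, which=1)
        pc2 = pct_mean_change(fits, individual_fits, which=2)
    else:
        pc1 = pc2 = np.nan
    return ScenarioSummary(
        power_pct=power(fits, alpha),
        fpr_pct=fpr(fits, alpha),
        bias_or1=bias_val,
        mean_or2=mean2,
        pct_change_or1=pc1,
        pct_change_or2=pc2,
        n_stable=n_stable,
        n_replicates=len(fits),
        or1_population=population_fit.or1,
        or2_population=population_fit.or2,
        alpha=alpha,
    )
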