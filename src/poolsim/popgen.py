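"""Synthetic birth-cohort generation and covariate measurement error.

The simulated population mimics an enriched-risk pregnancy cohort: each child
has a sex indicator ``z`` (1 = male, Bernoulli(0.5)), a true gestational age
``x_ga`` distributed as ``43 - chi2(3)`` weeks (one week is subtracted for a
random 5% of boys, reflecting shorter gestation among males), and two
standard-normal environmental exposures ``x1`` (causal) and ``x2``
(non-causal) with Pearson correlation ``rho`` = 0.7.

Exposures are observed with classical additive error, ``w_i = x_i + eps_i``
with ``eps_i ~ N(0, sigma2_i)`` independent of everything else.  Gestational
age is additionally reported in completed weeks: the noisy continuous value is
rounded to an integer and records outside the 23-43 week range are flagged
non-viable (dropped from all downstream sampling).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_generator, round_half_away
from .errors import ParameterError

#: column order of a fully populated individual-record frame
RECORD_COLUMNS = [
    "z", "x_ga", "x1", "x2",
    "w1", "w2", "w_ga",
    "y_latent", "y_star", "y_case", "viable",
]


@dataclass
class PopulationParams:
    """Parameters of the simulated cohort and its measurement-error model.

    Attributes
    ----------
    n_pop:
        Number of children generated (1,000,000 in the reference design).
    rho:
        Pearson correlation between the two standard-normal exposures.
    male_prob:
        Probability of ``z = 1``.
    ga_shift_frac:
        Fraction of males whose true gestational age is reduced by one week.
    sigma2_1, sigma2_2:
        Variances of the classical errors added to exposures 1 and 2.  The
        study grid uses ``sigma2_1`` in {0.0625, 0.25, 1} (6% of the true
        exposure variance up to error as large as the signal) and a fixed
        ``sigma2_2`` = 0.25.
    sigma2_ga:
        Variance (weeks^2) of the continuous error on gestational age, added
        before rounding to completed weeks.
    ga_range:
        Closed integer range of reportable gestational weeks; rounded values
        outside it mark the record non-viable (or are clamped, see
        ``ga_truncation``).
    ga_truncation:
        ``"drop"`` (default) marks out-of-range records non-viable; ``"clamp"``
        clips them to the range instead and keeps every record viable.
    seed:
        Root seed used when an operation is not handed an explicit generator.
    """

    n_pop: int = 1_000_000
    rho: float = 0.7
    male_prob: float = 0.5
    ga_shift_frac: float = 0.05
    sigma2_1: float = 0.0625
    sigma2_2: float = 0.25
    sigma2_ga: float = 1.72
    ga_range: tuple[int, int] = (23, 43)
    ga_truncation: str = "drop"
    seed: int = 0

    def validate(self) -> None:
        if self.n_pop < 0:
            raise ParameterError(f"n_pop must be >= 0, got {self.n_pop}")
        if not 0.0 <= abs(self.rho) <= 1.0 or abs(self.rho) > 1.0:
            raise ParameterError(f"|rho| must be <= 1, got {self.rho}")
        for name in ("sigma2_1", "sigma2_2", "sigma2_ga"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ParameterError(f"male_prob must be in [0,1], got {self.male_prob}")
        if not 0.0 <= self.ga_shift_frac <= 1.0:
            raise ParameterError(
                f"ga_shift_frac must be in [0,1], got {self.ga_shift_frac}"
            )
        lo, hi = self.ga_range
        if lo > hi:
            raise ParameterError(f"ga_range must be ordered, got {self.ga_range}")
        if self.ga_truncation not in ("drop", "clamp"):
            raise ParameterError(
                f"ga_truncation must be 'drop' or 'clamp', got {self.ga_truncation!r}"
            )


def simulate_population(params: PopulationParams, rng=None) -> pd.DataFrame:
    """Generate the truth covariates of a synthetic cohort.

    Returns a DataFrame with columns ``z`` (int8), ``x_ga``, ``x1``, ``x2``.
    Observed values and outcomes are filled in by later pipeline stages.

    Draw order (sex, gestational chi-square, male shift, exposures) is fixed,
    so a given generator state always yields a bit-identical population.
    """
    params.validate()
    rng = as_generator(params.seed if rng is None else rng)
    n = params.n_pop

    z = (rng.random(n) < params.male_prob).astype(np.int8)
    x_ga = 43.0 - rng.chisquare(3, n)
    # one-week reduction for a simple random fraction of boys
    shifted = (rng.random(n) < params.ga_shift_frac) & (z == 1)
    x_ga = x_ga - shifted

    # correlated standard-normal exposures via the Cholesky factor of
    # [[1, rho], [rho, 1]]
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    x1 = a
    x2 = params.rho * a + np.sqrt(1.0 - params.rho**2) * b

    return pd.DataFrame({"z": z, "x_ga": x_ga, "x1": x1, "x2": x2})


def apply_exposure_error(
    pop: pd.DataFrame, sigma2_1: float, sigma2_2: float, rng=None
) -> pd.DataFrame:
    """Fill ``w1 = x1 + eps1`` and ``w2 = x2 + eps2`` (classical error).

    The two error draws are independent of each other and of every truth
    field.  Zero variance reproduces the truth column exactly.
    """
    if sigma2_1 < 0 or sigma2_2 < 0:
        raise ParameterError("error variances must be >= 0")
    rng = as_generator(0 if rng is None else rng)
    n = len(pop)
    pop = pop.copy()
    pop["w1"] = pop["x1"].to_numpy() + np.sqrt(sigma2_1) * rng.standard_normal(n)
    pop["w2"] = pop["x2"].to_numpy() + np.sqrt(sigma2_2) * rng.standard_normal(n)
    return pop


def apply_gestational_error(
    pop: pd.DataFrame,
    sigma2_ga: float,
    ga_range: tuple[int, int] = (23, 43),
    rng=None,
    truncation: str = "drop",
) -> pd.DataFrame:
    """Fill ``w_ga`` = rounded noisy gestational age and its viability flag.

    ``w_ga = round(x_ga + eps_ga)`` with halves away from zero; records whose
    rounded week falls outside ``ga_range`` get ``ga_viable = False`` under
    ``truncation="drop"`` or are clipped into range under ``"clamp"``.
    """
    if sigma2_ga < 0:
        raise ParameterError("sigma2_ga must be >= 0")
    if truncation not in ("drop", "clamp"):
        raise ParameterError(f"unknown truncation mode {truncation!r}")
    rng = as_generator(0 if rng is None else rng)
    lo, hi = ga_range
    pop = pop.copy()
    noisy = pop["x_ga"].to_numpy() + np.sqrt(sigma2_ga) * rng.standard_normal(len(pop))
    w_ga = round_half_away(noisy)
    if truncation == "clamp":
        w_ga = np.clip(w_ga, lo, hi)
        viable = np.ones(len(pop), dtype=bool)
    else:
        viable = (w_ga >= lo) & (w_ga <= hi)
    pop["w_ga"] = w_ga
    pop["ga_viable"] = viable
    return pop
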