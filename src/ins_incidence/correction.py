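"""Under-reporting correction of surveyed case counts.

A hospital survey with response rate ``p`` (fraction of surveyed hospitals
that completed the survey) sees only the cases presenting at responding
hospitals.  Assuming reports go missing at random and independently, the
corrected ("true") case count is the plug-in estimator

    true = reported / p

Uncertainty is quantified by Monte Carlo: each replicate draws a case count
``k ~ Poisson(reported)`` and a response rate ``r = Binomial(n_units, p) /
n_units`` and forms ``k / r``; the 95% interval is the 2.5th-97.5th
percentile band of the replicates.  Replicates that draw ``r = 0`` are
redrawn, which keeps the replicate count exact and is a negligible event at
survey sizes of tens of hospitals with high response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import ResponseSurvey

__all__ = ["TrueCaseEstimate", "estimate_true_cases", "mc_true_cases"]

DEFAULT_N_SIMS = 1000


@dataclass(frozen=True)
class TrueCaseEstimate:
    """Corrected case count with Monte Carlo uncertainty."""

    reported: int
    response_rate: float
    point: float
    draws: np.ndarray = field(repr=False)
    ci_low: float
    ci_high: float
    n_sims: int
    seed: int


def estimate_true_cases(reported: float, response_rate: float) -> float:
    """Point estimate of the true case count: ``reported / response_rate``.

    ``response_rate`` is a fraction in (0, 1]; at full response the estimate
    is the reported count itself.
    """
    if reported < 0:
        raise ValueError(f"reported must be non-negative, got {reported}")
    if not 0 < response_rate <= 1:
        raise ValueError(f"response_rate must lie in (0, 1], got {response_rate}")
    return reported / response_rate


def mc_true_cases(
    reported: int,
    survey: ResponseSurvey,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> TrueCaseEstimate:
    """Monte Carlo corrected-count estimate with a 95% percentile interval.

    Parameters
    ----------
    reported
        Observed case count; the Poisson mean of the replicate counts.
    survey
        Survey ascertainment; the binomial has size ``survey.units_surveyed``
        and success probability ``survey.response_rate``.
    n_sims
        Number of Monte Carlo replicates (1000 by default).
    seed
        Seed for the PCG64 generator; identical seeds give bit-identical draws.

    Returns
    -------
    TrueCaseEstimate
        Point estimate ``reported / response_rate`` with empirical 2.5th and
        97.5th percentiles of the replicates (linear interpolation between
        order statistics).
    """
    if reported < 0:
        raise ValueError("reported must be non-negative")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p = survey.response_rate
    n_units = survey.units_surveyed
    if not 0 < p <= 1:
        raise ValueError("response_rate must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    k = rng.poisson(lam=reported, size=n_sims).astype(float)
    r = rng.binomial(n_units, p, size=n_sims) / n_units
    # redraw the (rare) zero-response replicates so every replicate is defined
    zero = r == 0
    while zero.any():
        r[zero] = rng.binomial(n_units, p, size=int(zero.sum())) / n_units
        zero = r == 0
    draws = k / r
    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    return TrueCaseEstimate(
        reported=int(reported),
        response_rate=p,
        point=estimate_true_cases(reported, p),
        draws=draws,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_sims=n_sims,
        seed=seed,
    )
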