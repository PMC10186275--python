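"""Two-proportion z-test for comparing incidence rates.

Rates are compared as proportions of person-time: the "trials" for a stratum
are its child-years at risk, ``children_at_risk * months / 12``, and the
"successes" its (corrected) case count.  The test statistic uses the pooled
proportion under the null of equal rates; a Yates-type continuity correction
(on by default) shrinks the absolute difference by half the sum of the
reciprocal denominators, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from scipy.stats import norm

__all__ = ["ComparisonResult", "two_proportion_test", "person_years"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-proportion z-test between two strata."""

    label_a: str
    label_b: str
    cases_a: float
    cases_b: float
    persons_a: float
    persons_b: float
    z: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def person_years(children_at_risk: float, months: float) -> float:
    """Annualised person-time: children at risk times years observed."""
    return children_at_risk * months / 12.0


def two_proportion_test(
    cases_a: float,
    persons_a: float,
    cases_b: float,
    persons_b: float,
    continuity_correction: bool = True,
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided two-proportion z-test on event counts per person-time.

    Parameters
    ----------
    cases_a, cases_b
        Event counts (may be corrected, hence real-valued).
    persons_a, persons_b
        Person-time denominators (child-years), strictly positive.
    continuity_correction
        Apply the Yates-type correction ``|p_a - p_b| - (1/n_a + 1/n_b)/2``
        (floored at 0).  The correction can only increase the p-value.

    Notes
    -----
    With equal observed rates the statistic is exactly zero and the p-value
    one; the result is symmetric under swapping the two groups.
    """
    if persons_a <= 0 or persons_b <= 0:
        raise ValueError("person-time denominators must be positive")
    if not (0 <= cases_a <= persons_a and 0 <= cases_b <= persons_b):
        raise ValueError("case counts must lie within [0, person-time]")

    pa = cases_a / persons_a
    pb = cases_b / persons_b
    pooled = (cases_a + cases_b) / (persons_a + persons_b)
    se = sqrt(pooled * (1.0 - pooled) * (1.0 / persons_a + 1.0 / persons_b))

    diff = abs(pa - pb)
    if continuity_correction:
        diff = max(0.0, diff - 0.5 * (1.0 / persons_a + 1.0 / persons_b))

    if se == 0.0:
        z = 0.0
        p_value = 1.0
    else:
        z = diff / se
        p_value = float(2.0 * norm.sf(z))
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        cases_a=cases_a,
        cases_b=cases_b,
        persons_a=persons_a,
        persons_b=persons_b,
        z=z,
        p_value=min(1.0, p_value),
        alpha=alpha,
    )
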