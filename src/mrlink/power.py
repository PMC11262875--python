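"""Analytic power for a binary-outcome two-sample MR design.

The non-centrality of the Wald test of the causal log-odds ratio is
approximated by

    z = |ln OR| * sqrt(N * R^2 * K * (1 - K))

where N is the outcome-study sample size, K its case fraction and R^2 the
variance of the exposure explained by the instruments.  Power at two-sided
level alpha is Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2}).  This is
the closed form behind the widely used mRnd-style online calculators; it is
an approximation, and small discrepancies with other tools trace to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats

__all__ = ["PowerInputs", "power_binary", "minimal_detectable_or"]


@dataclass(frozen=True)
class PowerInputs:
    n_outcome: int
    case_fraction: float
    r_squared_exposure: float
    odds_ratio: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0.0 < self.r_squared_exposure < 1.0:
            raise ValueError("r_squared_exposure must lie in (0, 1)")
        if self.odds_ratio <= 0.0:
            raise ValueError("odds_ratio must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def power_binary(inputs: PowerInputs) -> float:
    """Power to detect the hypothesized odds ratio.

    Symmetric in OR <-> 1/OR, equals alpha at OR = 1, and increases to 1
    with sample size, explained variance and effect size.
    """
    inputs.validate()
    z = abs(math.log(inputs.odds_ratio)) * math.sqrt(
        inputs.n_outcome
        * inputs.r_squared_exposure
        * inputs.case_fraction
        * (1.0 - inputs.case_fraction)
    )
    z_crit = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    return float(stats.norm.cdf(z - z_crit) + stats.norm.cdf(-z - z_crit))


def minimal_detectable_or(
    n_outcome: int,
    case_fraction: float,
    r_squared_exposure: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest OR > 1 detectable at the requested power."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")

    def gap(log_or: float) -> float:
        return (
            power_binary(
                PowerInputs(n_outcome, case_fraction, r_squared_exposure, math.exp(log_or), alpha)
            )
            - target_power
        )

    return float(math.exp(optimize.brentq(gap, 1e-9, 10.0)))
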