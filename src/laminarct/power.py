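"""Power and sample size for comparing two independent correlations.

The test is the two-sided Fisher r-to-z comparison: with q = atanh(r1) -
atanh(r2) and SE = sqrt(1/(n1-3) + 1/(n2-3)), the null is rejected when
|q_hat / SE| > z_{alpha/2}.  Analytic power is

    Phi(|q|/SE - z_{alpha/2}) + Phi(-|q|/SE - z_{alpha/2}),

the second term being the (usually negligible) far-tail rejection
probability.  A Monte-Carlo routine cross-validates the analytic formula by
drawing bivariate-normal cohorts and applying the same test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "power_two_correlations", "n_for_power",
           "simulate_power"]


@dataclass(frozen=True)
class PowerSpec:
    r1: float
    r2: float
    alpha: float = 0.05
    power_target: float = 0.80
    n1: int = 17
    n2: int = 16
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (abs(self.r1) < 1 and abs(self.r2) < 1):
            raise ValueError("|r| must be < 1")
        if not (0 < self.alpha < 1 and 0 < self.power_target < 1):
            raise ValueError("alpha and power_target must lie in (0, 1)")


def power_two_correlations(r1: float, r2: float, n1: int, n2: int,
                           alpha: float = 0.05) -> float:
    """Analytic power of the two-sided Fisher-z test at given group sizes."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("group sizes must exceed 3 (n - 3 > 0)")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("|r| must be < 1")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    lam = abs(np.arctanh(r1) - np.arctanh(r2)) / se
    z_crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(lam - z_crit) + stats.norm.cdf(-lam - z_crit))


def n_for_power(r1: float, r2: float, power_target: float = 0.80,
                alpha: float = 0.05) -> int:
    """Smallest equal per-group n reaching the target power.

    Closed-form start n0 = 2 ((z_{alpha/2} + z_power) / q)^2 + 3 with
    q = atanh(r1) - atanh(r2), refined by exact integer search so that the
    returned n meets the target and n - 1 does not (unless n = 4, the
    smallest admissible size).
    """
    if r1 == r2:
        raise ValueError("r1 == r2: no finite sample size reaches the target")
    q = abs(np.arctanh(r1) - np.arctanh(r2))
    z_a = stats.norm.isf(alpha / 2.0)
    z_b = stats.norm.ppf(power_target)
    n = max(4, int(np.ceil(2.0 * ((z_a + z_b) / q) ** 2 + 3.0)))
    while n > 4 and power_two_correlations(r1, r2, n - 1, n - 1, alpha) >= power_target:
        n -= 1
    while power_two_correlations(r1, r2, n, n, alpha) < power_target:
        n += 1
    return n


def simulate_power(spec: PowerSpec):
    """Monte-Carlo power of the Fisher-z comparison.

    Draws ``n_sims`` pairs of bivariate-normal cohorts with true
    correlations (r1, r2) at sizes (n1, n2), applies the two-sided Fisher-z
    test at ``alpha``, and returns (power, binomial SE).
    """
    if spec.n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    rng = np.random.default_rng(spec.seed)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    se = np.sqrt(1.0 / (spec.n1 - 3) + 1.0 / (spec.n2 - 3))

    def sample_r(rho, n):
        x = rng.standard_normal((spec.n_sims, n))
        e = rng.standard_normal((spec.n_sims, n))
        y = rho * x + np.sqrt(1.0 - rho ** 2) * e
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        return (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))

    z = (np.arctanh(sample_r(spec.r1, spec.n1))
         - np.arctanh(sample_r(spec.r2, spec.n2))) / se
    reject = np.abs(z) > z_crit
    p_hat = float(reject.mean())
    return p_hat, float(np.sqrt(p_hat * (1.0 - p_hat) / spec.n_sims))
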