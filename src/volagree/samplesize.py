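"""Reliability-study sample size by the ICC confidence-interval lower-limit
(assurance) procedure.

The study succeeds when the one-sided (1−α) lower confidence limit of the
one-way random-effects ICC exceeds a minimum acceptable value ρ₀; the
required sample size is the smallest n for which this happens with at least
the target probability (assurance) when the true ICC is ρ.

With θ = ρ/(1−ρ), the one-way ANOVA F statistic for n subjects and m raters
satisfies F/(1+mθ) ~ F(n−1, n(m−1)), and the lower confidence limit exceeds
ρ₀ exactly when F > (1+mθ₀)·F_{1−α; n−1, n(m−1)}.  The assurance therefore
has the closed form

    power(n) = P( F(n−1, n(m−1)) > (1+mθ₀)/(1+mθ) · F_{1−α; n−1, n(m−1)} ),

evaluated with the exact F distribution (no normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeSpec", "lower_limit_power", "required_sample_size"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters of the assurance calculation.

    rho: anticipated true ICC; rho0: minimum acceptable ICC; power: target
    assurance probability; alpha: one-sided level of the lower confidence
    limit; m: number of raters per subject.
    """

    rho: float = 0.9
    rho0: float = 0.8
    power: float = 0.8
    alpha: float = 0.05
    m: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.rho0 < self.rho < 1:
            raise ValueError("need 0 ≤ rho0 < rho < 1")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be a one-sided level in (0, 0.5)")
        if not 0.5 <= self.power < 1:
            raise ValueError("power target must be in [0.5, 1)")
        if self.m < 2:
            raise ValueError("need at least 2 raters")


def lower_limit_power(n: int, spec: SampleSizeSpec) -> float:
    """Probability that the one-sided lower ICC confidence limit exceeds ρ₀."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    theta = spec.rho / (1 - spec.rho)
    theta0 = spec.rho0 / (1 - spec.rho0)
    d1, d2 = n - 1, n * (spec.m - 1)
    crit = (1 + spec.m * theta0) / (1 + spec.m * theta) * stats.f.ppf(1 - spec.alpha, d1, d2)
    return float(stats.f.sf(crit, d1, d2))


def required_sample_size(spec: SampleSizeSpec, max_n: int = 10**6) -> int:
    """Smallest n with assurance ≥ the target (power is monotone in n).

    Exponential search followed by bisection keeps the number of F-quantile
    evaluations logarithmic even for extreme specifications.
    """
    lo, hi = 2, 2
    while lower_limit_power(hi, spec) < spec.power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise ValueError(f"assurance target unreachable below n = {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if lower_limit_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return hi
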