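"""Case-control genetic sample-size calculation under an additive model.

The design is an allele-based two-proportion test: the expected
risk-allele frequency among cases is obtained by retrospective
multiplicative tilting of the population frequency,

    q_case = q * RR / (1 + q * (RR - 1)),

controls carry the population (Hardy-Weinberg) frequency q, and the
per-group sample size is the smallest n for which the pooled two-proportion
z-test on 2n alleles reaches the target power at the stated alpha.
Imperfect marker-disease linkage disequilibrium inflates n by 1/r^2.

Disease prevalence enters only through an opt-in unaffected-control
adjustment (``unaffected_controls=True``), which depletes the risk allele
among controls; it raises when the requested risk ratio and prevalence are
jointly infeasible (implied control frequency below zero) - which is the
case for large risk ratios at prevalences near one half, so the feasible
population-control design is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Assumptions for the sample-size calculation."""

    genetic_risk_ratio: float
    maf: float
    prevalence: float = 0.477
    power: float = 0.80
    alpha: float = 0.05
    model: str = "additive"
    ld: float = 1.0  # r^2 between marker and risk allele
    unaffected_controls: bool = False

    def validate(self) -> None:
        if self.genetic_risk_ratio <= 0:
            raise ValueError("genetic_risk_ratio must be positive")
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")
        for name in ("prevalence", "power", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.model != "additive":
            raise ValueError(f"only the additive model is supported, got {self.model!r}")
        if not 0 < self.ld <= 1:
            raise ValueError("ld r^2 must be in (0, 1]")


def expected_allele_frequencies(spec: PowerSpec) -> tuple[float, float]:
    """Expected risk-allele frequencies in (cases, controls)."""
    spec.validate()
    q, rr = spec.maf, spec.genetic_risk_ratio
    q_case = q * rr / (1.0 + q * (rr - 1.0))
    if spec.unaffected_controls:
        k = spec.prevalence
        q_control = (q - k * q_case) / (1.0 - k)
        if q_control <= 0:
            raise ValueError(
                "risk ratio and prevalence jointly infeasible: implied "
                "unaffected-control allele frequency <= 0"
            )
    else:
        q_control = q
    return q_case, q_control


def required_n(spec: PowerSpec) -> float:
    """Smallest per-group sample size (persons) meeting the target power.

    Returns ``math.inf`` when the risk ratio is 1 (null effect).  The
    count is ceiling-rounded; each person contributes two alleles.
    """
    spec.validate()
    if spec.genetic_risk_ratio == 1.0:
        return math.inf
    p1, p2 = expected_allele_frequencies(spec)
    diff = p1 - p2
    p_bar = (p1 + p2) / 2.0
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    numerator = (
        z_a * math.sqrt(2.0 * p_bar * (1.0 - p_bar))
        + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2
    n_alleles = numerator / (diff * diff) / spec.ld
    return math.ceil(n_alleles / 2.0)


def simulate_power(
    spec: PowerSpec, n_per_group: int, n_reps: int = 2000, seed: int = 0
) -> float:
    """Empirical power of the pooled two-proportion z-test at ``n_per_group``.

    Simulates allele counts at the design's expected case/control
    frequencies and applies the same test the sample-size formula targets.
    """
    import numpy as np

    if n_per_group <= 0 or not math.isfinite(n_per_group):
        raise ValueError("n_per_group must be a positive finite count")
    p1, p2 = expected_allele_frequencies(spec)
    rng = np.random.default_rng(seed)
    m = 2 * n_per_group  # alleles per group
    x1 = rng.binomial(m, p1, size=n_reps)
    x2 = rng.binomial(m, p2, size=n_reps)
    phat1, phat2 = x1 / m, x2 / m
    pooled = (x1 + x2) / (2 * m)
    se = np.sqrt(pooled * (1 - pooled) * (2 / m))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (phat1 - phat2) / se, 0.0)
    crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(np.mean(np.abs(z) > crit))
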