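"""Sample-size and power arithmetic for allelic case-control tests.

For a two-sided allelic test at level ``alpha`` and power ``1 - beta``,
detecting a case-control allele-frequency difference ``d`` at population
allele frequency ``x = (mA + mU)/2`` requires about

    N = (z*_alpha + z_beta)^2 * x * (1 - x) / d^2

case-control pairs, where ``z*_alpha`` is the two-sided alpha point of the
standard normal (upper alpha/2 quantile) and ``z_beta`` the upper beta
point.  The split form carries the exact per-group variance factor
``gamma = sqrt(2x(1-x) - d^2/2)``; for the d values relevant here the
approximation ``gamma ~ sqrt(2x(1-x))`` is good to <0.2% and the collapsed
form above is the default.  N is maximal at the worst-case frequency
x = 0.5, which is where genome-wide lower bounds are quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtri

__all__ = [
    "PowerDesign",
    "normal_quantile",
    "gamma_factor",
    "required_pairs",
    "min_detectable_d",
]

#: Genome-wide significance level used for GWAS-scale bounds (two-sided).
GENOME_WIDE_ALPHA = 2.5e-7


@dataclass(frozen=True)
class PowerDesign:
    """A two-sided allelic association design.

    alpha : two-sided type-I error probability
    power : 1 - beta
    x     : population frequency of the tested allele, (mA + mU)/2
    d     : case-control allele-frequency difference to detect
    """

    alpha: float
    power: float
    x: float
    d: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        if not 0.0 < self.x < 1.0:
            raise ValueError(f"x must lie in (0, 1), got {self.x}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")


def normal_quantile(upper_tail_prob: float) -> float:
    """z with P(Z > z) = ``upper_tail_prob`` for standard normal Z.

    Backed by scipy's inverse normal CDF (``ndtri``), which is accurate far
    beyond 1e-9 across the full open interval — tail accuracy matters
    because genome-wide alphas sit near 1e-7.
    """
    if not 0.0 < upper_tail_prob < 1.0:
        raise ValueError(f"probability must lie in (0, 1), got {upper_tail_prob}")
    return float(-ndtri(upper_tail_prob))


def gamma_factor(x: float, d: float, approximate: bool = False) -> float:
    """Per-pair standard-deviation factor sqrt(2x(1-x) - d^2/2).

    With ``approximate=True`` returns sqrt(2x(1-x)) (the d^2 term dropped);
    the relative error of the approximation is below 0.2% whenever
    d^2 < 0.004 * 2x(1-x), which holds for threshold-scale d.
    """
    base = 2.0 * x * (1.0 - x)
    if approximate:
        return math.sqrt(base)
    g2 = base - 0.5 * d * d
    if g2 <= 0:
        raise ValueError(f"gamma^2 must be positive: 2x(1-x)={base}, d={d}")
    return math.sqrt(g2)


def required_pairs(design: PowerDesign, form: str = "collapsed") -> float:
    """Required number of case-control pairs N for the design.

    form="collapsed" (default) evaluates
    ``(z*_alpha + z_beta)^2 * x(1-x) / d^2``; form="split" keeps the exact
    gamma term: ``0.5 * (z*_alpha*sqrt(2x(1-x)) + z_beta*gamma)^2 / d^2``.
    The two agree to the gamma approximation's error.  Round the result to
    two significant figures for presentation with
    :func:`pcriterion.model.round_sig`.
    """
    z_alpha = normal_quantile(design.alpha / 2.0)
    z_beta = normal_quantile(1.0 - design.power)
    if form == "collapsed":
        return (z_alpha + z_beta) ** 2 * design.x * (1.0 - design.x) / design.d**2
    if form == "split":
        g_approx = gamma_factor(design.x, design.d, approximate=True)
        g_exact = gamma_factor(design.x, design.d)
        return 0.5 * (z_alpha * g_approx + z_beta * g_exact) ** 2 / design.d**2
    raise ValueError(f"unknown form {form!r}; use 'collapsed' or 'split'")


def min_detectable_d(N: float, alpha: float, power: float, x: float) -> float:
    """Smallest detectable d with N pairs: inverse of :func:`required_pairs`.

    d = (z*_alpha + z_beta) * sqrt(x(1-x)/N).
    """
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    if not 0.0 < x < 1.0:
        raise ValueError(f"x must lie in (0, 1), got {x}")
    z_alpha = normal_quantile(alpha / 2.0)
    z_beta = normal_quantile(1.0 - power)
    return (z_alpha + z_beta) * math.sqrt(x * (1.0 - x) / N)
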