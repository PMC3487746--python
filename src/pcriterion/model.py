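"""Epidemiological parameters and the persistence threshold ``nu``.

A heritable disease under strong negative selection can only persist at a
stable prevalence if each nuclear risk locus is maintained by
mutation-selection balance.  That balance caps the case-control difference
``d = mA - mU`` of the risk-allele frequency at

    nu = (1 - s*p) * mu / ((1 - p) * s * p)

where ``p`` is the prevalence of the disease, ``s`` the selection
coefficient of affected individuals (1 minus their mean relative fitness)
and ``mu`` the per-locus per-generation mutation rate.  A genuine nuclear
susceptibility allele must satisfy ``0 < d < nu``; an associated allele
with ``d >= nu`` cannot be sustained as a risk allele and is instead a
protective allele (its carriers among cases are less severely selected
against).

All quantities are carried at full floating precision; display rounding
(3 significant figures) is a presentation concern only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "PopulationParams",
    "MutationSpec",
    "CriterionThreshold",
    "MU_PRESETS",
    "DEFAULT_PARAMS",
    "compute_nu",
    "mu_upper_bound",
    "expected_affected_total",
    "round_sig",
    "load_config",
]


def round_sig(x: float, n_digits: int) -> float:
    """Round ``x`` to ``n_digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_digits - 1 - exponent)


@dataclass(frozen=True)
class PopulationParams:
    """Disease prevalence ``p`` and selection coefficient ``s``.

    Defaults are the schizophrenia estimates from the large Finnish cohort
    literature: p = 1.29e-2, s = 6.54e-1.  Both are dimensionless; ``s`` is
    1 minus the mean relative reproductive fitness of affected individuals.
    """

    prevalence: float = 1.29e-2
    selection_coefficient: float = 6.54e-1

    def __post_init__(self) -> None:
        p, s = self.prevalence, self.selection_coefficient
        if not 0.0 < p < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {p}")
        if not 0.0 < s <= 1.0:
            raise ValueError(f"selection coefficient must lie in (0, 1], got {s}")
        if s * p >= 1.0:
            raise ValueError(f"s*p must be < 1, got {s * p}")


#: Per-locus per-generation mutation-rate presets for nuclear loci
#: (autosomes and X): the literature average, the parental-age-scaled
#: upper bound 29.6/20 * 1e-4, and a relatively low rate.
MU_PRESETS: dict[str, float] = {
    "average": 1.48e-5,
    "highest": 1.48e-4,
    "low": 1.48e-6,
}

DEFAULT_PARAMS = PopulationParams()


@dataclass(frozen=True)
class MutationSpec:
    """Per-locus mutation rate, optionally derived from parental age.

    Nuclear per-locus rates scale roughly linearly with mean parental age;
    ``base_rate_per_generation`` is the rate at one generation-equivalent
    (``generation_years``) of parental age.
    """

    mu: float
    mean_parental_age: Optional[float] = None
    generation_years: float = 20.0
    base_rate_per_generation: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")

    @classmethod
    def from_parental_age(
        cls,
        mean_parental_age: float,
        base_rate_per_generation: float,
        generation_years: float = 20.0,
    ) -> "MutationSpec":
        mu = mu_upper_bound(mean_parental_age, generation_years, base_rate_per_generation)
        return cls(
            mu=mu,
            mean_parental_age=mean_parental_age,
            generation_years=generation_years,
            base_rate_per_generation=base_rate_per_generation,
        )


@dataclass(frozen=True)
class CriterionThreshold:
    """The persistence threshold ``nu`` with its parameter provenance."""

    nu: float
    params_used: PopulationParams
    mu_used: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be positive, got {self.nu}")

    @property
    def display(self) -> float:
        """``nu`` rounded to 3 significant figures, for reporting only."""
        return round_sig(self.nu, 3)


def compute_nu(params: PopulationParams, mu: float) -> CriterionThreshold:
    """Persistence threshold nu = (1 - s*p) * mu / ((1 - p) * s * p).

    Per generation, selection removes at most ``p*(1-p)*d*s/(1-s*p)`` of a
    risk allele's population frequency while mutation replenishes at most
    ``mu``; equating the two bounds ``d`` by ``nu``.  The value is returned
    unrounded — classification against a pre-rounded threshold misorders
    boundary variants.

    Parameters
    ----------
    params
        Prevalence and selection coefficient.
    mu
        Per-locus per-generation mutation rate, in (0, 1).
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must lie in (0, 1), got {mu}")
    p = params.prevalence
    s = params.selection_coefficient
    nu = (1.0 - s * p) * mu / ((1.0 - p) * s * p)
    return CriterionThreshold(nu=nu, params_used=params, mu_used=mu)


def mu_from_nu(nu: float, params: PopulationParams) -> float:
    """Invert :func:`compute_nu`: the mutation rate implying threshold ``nu``."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    p = params.prevalence
    s = params.selection_coefficient
    return nu * (1.0 - p) * s * p / (1.0 - s * p)


def mu_upper_bound(
    mean_parental_age: float,
    generation_years: float = 20.0,
    base_rate: float = 1.0e-4,
) -> float:
    """Parental-age-scaled upper bound on the per-locus mutation rate.

    Returns ``mean_parental_age / generation_years * base_rate``; with the
    observed mean parental age of 29.6 years, a 20-year generation and a
    1e-4 ceiling this gives 1.48e-4.
    """
    if mean_parental_age <= 0 or generation_years <= 0 or base_rate <= 0:
        raise ValueError("all inputs must be positive")
    return mean_parental_age / generation_years * base_rate


def expected_affected_total(world_population: float, prevalence: float) -> float:
    """Expected number of affected individuals: population times prevalence.

    With ~7e9 people and a 0.7% prevalence this is ~4.9e7.  The raw product
    is returned; round with :func:`round_sig` for presentation.
    """
    if world_population <= 0 or prevalence <= 0:
        raise ValueError("inputs must be positive")
    return world_population * prevalence


def load_config(path: str | Path) -> dict:
    """Read a YAML key-value config (keys: preset, p, s, mu).

    Returns a dict with resolved ``params`` (:class:`PopulationParams`) and
    ``mu`` (float or None).  ``preset`` names a mutation-rate preset from
    :data:`MU_PRESETS`; an explicit ``mu`` key overrides it.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a key-value mapping, got {type(raw).__name__}")
    params = PopulationParams(
        prevalence=float(raw.get("p", DEFAULT_PARAMS.prevalence)),
        selection_coefficient=float(raw.get("s", DEFAULT_PARAMS.selection_coefficient)),
    )
    mu: Optional[float] = None
    if "preset" in raw:
        preset = raw["preset"]
        if preset not in MU_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(MU_PRESETS)}")
        mu = MU_PRESETS[preset]
    if "mu" in raw:
        mu = float(raw["mu"])
    return {"params": params, "mu": mu}
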