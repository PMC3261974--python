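"""Prevalence of undernourishment (PoU) from the FAO distribution framework.

Within-population habitual calorie intake is modelled as lognormal with
mean equal to the per capita dietary energy supply (DES, kcal/person/day)
and a given coefficient of variation (CV). The PoU is the mass of that
distribution below the population-average minimum dietary energy
requirement (MDER):

    sigma^2 = ln(1 + CV^2),   mu = ln(DES) - sigma^2 / 2,
    PoU = F_lognormal(MDER; mu, sigma)

In projections the CV and MDER are always held at their baseline values
— only calorie availability is scenario-dependent — because no
projections of intake inequality or requirements exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import lognorm

__all__ = [
    "IntakeDistribution",
    "lognormal_params",
    "estimate_pou",
    "project_pou",
    "solve_des",
]


@dataclass(frozen=True)
class IntakeDistribution:
    """Lognormal calorie-intake distribution, mean-preserving in DES."""

    des: float  # mean per capita dietary energy supply, kcal/person/day
    cv: float  # coefficient of variation of habitual intake
    mu: float  # log-scale location
    sigma: float  # log-scale spread

    def cdf(self, kcal: float) -> float:
        return float(lognorm.cdf(kcal, s=self.sigma, scale=math.exp(self.mu)))


def lognormal_params(des: float, cv: float) -> IntakeDistribution:
    """The unique lognormal with mean ``des`` and coefficient of variation ``cv``."""
    if not des > 0:
        raise ValueError(f"des must be positive, got {des}")
    if not cv > 0:
        raise ValueError(f"cv must be positive, got {cv}")
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(des) - sigma * sigma / 2.0
    return IntakeDistribution(des=des, cv=cv, mu=mu, sigma=sigma)


def estimate_pou(des: float, cv: float, mder: float) -> float:
    """Proportion of the population with habitual intake below ``mder``.

    Strictly decreasing in ``des`` and strictly increasing in ``mder``;
    always inside (0, 1) for finite positive inputs.
    """
    if not mder > 0:
        raise ValueError(f"mder must be positive, got {mder}")
    return lognormal_params(des, cv).cdf(mder)


def project_pou(scenario) -> float:
    """PoU for a :class:`~stuntcast.panel.ScenarioInput`.

    Uses the scenario's calorie availability with the *baseline* CV and
    MDER, whatever the scenario.
    """
    return estimate_pou(scenario.kcal_pc_day, scenario.cv_baseline, scenario.mder)


def solve_des(target_pou: float, cv: float, mder: float,
              bracket: tuple[float, float] = (1.0, 1e6), xtol: float = 1e-9) -> float:
    """Invert :func:`estimate_pou` for the DES giving a target PoU.

    Root-finds on ``des`` (Brent's method), so it stays valid if the
    intake CDF family is swapped out. Used to back-solve baseline
    calorie availability from an observed undernourishment prevalence.
    """
    if not 0.0 < target_pou < 1.0:
        raise ValueError(f"target_pou must be in (0, 1), got {target_pou}")
    lo, hi = bracket
    f = lambda des: estimate_pou(des, cv, mder) - target_pou
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(f"bracket {bracket} does not straddle PoU={target_pou}")
    return float(brentq(f, lo, hi, xtol=xtol))
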