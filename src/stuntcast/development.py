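"""The development score: a 0–1 index of nonfood causes of stunting.

Nonfood causes — sanitation, maternal education, health-care access and
the rest of the socioeconomic cluster — are proxied by per capita GDP and
income inequality. The score ``w`` equals 0 where socioeconomic
conditions no longer contribute to stunting (per capita GDP of $10,000
in 2000 US$ with a Gini of 0.38, beyond which conditions are treated as
saturated) and 1 at the worst socioeconomic conditions observed in the
baseline calibration panel.

Functional form. GDP and Gini are collapsed into an inequality-adjusted
income ``a = gdp_pc * (1 - gini)``, and the score interpolates linearly
in log income between the saturation point and the baseline worst:

    w = clamp( [ln(a_opt) - ln(a)] / [ln(a_opt) - ln(a_worst)], 0, 1 )

with ``a_opt = gdp_saturation * (1 - gini_saturation)``. Log income is
the standard scale for income–health gradients; the form honours every
stated property of the score (0–1 range, both endpoints, saturation,
monotone in both drivers) and is kept behind this module's surface so an
alternative index can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DevelopmentAnchors",
    "adjusted_income",
    "calibrate_anchors",
    "unsaturated_anchors",
    "development_score",
]

GDP_SATURATION_DEFAULT = 10_000.0  # 2000 US$/person/year
GINI_SATURATION_DEFAULT = 0.38


@dataclass(frozen=True)
class DevelopmentAnchors:
    """Calibration constants mapping (GDP, Gini) to the score.

    ``adjusted_income_worst`` is the minimum inequality-adjusted income
    in the calibration panel — the baseline global maximum of nonfood
    causes, where the score equals 1.
    """

    adjusted_income_worst: float
    gdp_saturation: float = GDP_SATURATION_DEFAULT
    gini_saturation: float = GINI_SATURATION_DEFAULT

    def __post_init__(self):
        if not (self.adjusted_income_worst > 0 and self.gdp_saturation > 0):
            raise ValueError("income anchors must be positive")
        if not 0.0 <= self.gini_saturation < 1.0:
            raise ValueError("gini_saturation must lie in [0, 1)")
        if not self.adjusted_income_worst < self.adjusted_income_optimal:
            raise ValueError(
                "adjusted_income_worst must lie below the saturation income "
                f"({self.adjusted_income_worst} >= {self.adjusted_income_optimal})"
            )

    @property
    def adjusted_income_optimal(self) -> float:
        return self.gdp_saturation * (1.0 - self.gini_saturation)


def adjusted_income(gdp_pc, gini):
    """Inequality-adjusted income ``gdp_pc * (1 - gini)``.

    Strictly increasing in GDP, strictly decreasing in Gini. Accepts
    scalars or arrays; a Gini of 1 (all income to one person) is
    degenerate and rejected.
    """
    gdp_pc = np.asarray(gdp_pc, dtype=float)
    gini = np.asarray(gini, dtype=float)
    if np.any(gdp_pc <= 0):
        raise ValueError("gdp_pc must be positive")
    if np.any((gini < 0) | (gini >= 1)):
        raise ValueError("gini must lie in [0, 1)")
    out = gdp_pc * (1.0 - gini)
    return float(out) if out.ndim == 0 else out


def calibrate_anchors(
    panel: Sequence,
    gdp_saturation: float = GDP_SATURATION_DEFAULT,
    gini_saturation: float = GINI_SATURATION_DEFAULT,
) -> DevelopmentAnchors:
    """Fix the score's worst-case anchor from a baseline panel.

    The anchor is the minimum adjusted income over the panel's
    (gdp_pc, gini) pairs; the saturation constants pass through.
    """
    if not len(panel):
        raise ValueError("cannot calibrate anchors on an empty panel")
    worst = min(adjusted_income(r.gdp_pc, r.gini) for r in panel)
    return DevelopmentAnchors(
        adjusted_income_worst=worst,
        gdp_saturation=gdp_saturation,
        gini_saturation=gini_saturation,
    )


def unsaturated_anchors(panel: Sequence, anchors: DevelopmentAnchors) -> DevelopmentAnchors:
    """Anchors with the saturation assumption disabled.

    Replaces the fixed $10,000/0.38 optimum with the best adjusted
    income actually observed in the panel, for sensitivity analysis of
    the saturation assumption (the score then spans the panel's own
    income range instead of saturating at the fixed point).
    """
    if not len(panel):
        raise ValueError("empty panel")
    best = max(adjusted_income(r.gdp_pc, r.gini) for r in panel)
    # express the panel-best optimum as a zero-Gini saturation income
    return replace(anchors, gdp_saturation=best, gini_saturation=0.0)


def development_score(gdp_pc, gini, anchors: DevelopmentAnchors):
    """Nonfood-cause score ``w`` in [0, 1] for (GDP, Gini).

    0 at (or beyond) the saturation point, 1 at (or below) the baseline
    worst anchor; log-linear in adjusted income between. Non-increasing
    in GDP at fixed Gini and non-decreasing in Gini at fixed GDP.
    Scalars or arrays.
    """
    a = adjusted_income(gdp_pc, gini)
    a_opt = anchors.adjusted_income_optimal
    a_worst = anchors.adjusted_income_worst
    w = (np.log(a_opt) - np.log(a)) / (np.log(a_opt) - np.log(a_worst))
    w = np.clip(w, 0.0, 1.0)
    return float(w) if np.ndim(w) == 0 else w
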