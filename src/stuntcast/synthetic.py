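"""Synthetic country-year panels and scenario inputs with known ground truth.

Real calibration data for this model is a merged national dataset
(undernourishment prevalence, stunting surveys, GDP, Gini) that cannot
be redistributed and is laborious to reassemble; the generator instead
draws panels with the same statistical structure the model assumes, so
the full pipeline — beta percentile estimation, the two-step attribution
fit, Monte Carlo projection — is exercised end to end against a known
generating surface.

Covariates (undernourishment x, GDP, Gini) are drawn independently over
ranges matching the observed global panel (GDP $81–$5,513, Gini
0.17–0.74, PoU 5–70%). GDP is log-uniform — national income is
right-skewed, and the log-uniform mean over this range (≈$1,290) sits
near the observed panel mean (≈$900) where a uniform draw would not —
while undernourishment and Gini are uniform over their ranges. Stunting
is the bilinear surface
at the generating parameters plus Gaussian level noise, resampled (not
clipped) until the proportions are feasible, so there are no point
masses at the bounds. Scenario inputs back-solve baseline calories from
each country's undernourishment via the intake distribution, then apply
per-scenario multiplicative calorie shifts; the two climate scenarios
default to 12–13% less food than the no-climate-change future, enough to
roughly double undernourishment in poor regions, which is the magnitude
of shift the model is meant to interrogate. Scenario generation covers
only low-income countries (baseline GDP below ``scenario_gdp_max``),
mirroring the low-income regional focus of stunting projection —
high-income countries project past development-score saturation, where
the model is explicitly outside its fitted range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .development import DevelopmentAnchors, calibrate_anchors, development_score
from .model import StuntingParams, default_params
from .panel import CountryYearRecord, ScenarioInput
from .undernourishment import estimate_pou, solve_des

__all__ = ["SyntheticConfig", "GroundTruth", "ScenarioTruth", "generate_panel", "generate_scenarios"]

REGION_NAMES = ("South Asia", "SSA Central", "SSA East", "SSA South", "SSA West")
MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the global calibration panel (186 records; covariate
    ranges as observed) and the published central parameters as the
    generating truth. ``residual_sd`` is proportion-scale noise per
    level; 0.02 matches the dispersion left after the bilinear surface.
    """

    n_records: int = 186
    n_countries: int = 62
    n_regions: int = 5
    true_params: StuntingParams = field(default_factory=default_params)
    residual_sd: tuple[float, float] = (0.02, 0.02)  # (moderate, severe)
    gdp_range: tuple[float, float] = (81.0, 5513.0)
    gini_range: tuple[float, float] = (0.17, 0.74)
    pou_range: tuple[float, float] = (0.05, 0.70)
    year_range: tuple[int, int] = (1988, 2008)
    cv_range: tuple[float, float] = (0.20, 0.35)
    mder_range: tuple[float, float] = (1700.0, 1900.0)
    scenario_effects: Mapping[str, float] = field(
        default_factory=lambda: {"noCC": 1.0, "NCAR": 0.87, "CSIRO": 0.88}
    )
    gdp_growth_range: tuple[float, float] = (2.0, 6.0)  # per-region multiplier to horizon
    scenario_gdp_max: float = 800.0  # baseline GDP cap for scenario countries
    pop_range: tuple[float, float] = (5e5, 5e7)  # under-5 population
    seed: int = 0

    def __post_init__(self):
        if self.n_records < self.n_countries:
            raise ValueError("n_records must be at least n_countries")
        for name in ("gdp_range", "gini_range", "pou_range", "cv_range", "mder_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is not an interval: {(lo, hi)}")
        if not (0 <= self.gini_range[0] and self.gini_range[1] < 1):
            raise ValueError("gini_range must lie within [0, 1)")
        if not (0 < self.pou_range[0] and self.pou_range[1] <= 1):
            raise ValueError("pou_range must lie within (0, 1]")


class GroundTruth(NamedTuple):
    params: StuntingParams
    anchors: DevelopmentAnchors


def _region_name(i: int) -> str:
    return REGION_NAMES[i] if i < len(REGION_NAMES) else f"Region {i + 1}"


def generate_panel(config: SyntheticConfig) -> tuple[list[CountryYearRecord], GroundTruth]:
    """Draw a country-year panel lying on the generating surface plus noise.

    Countries are assigned cyclically to regions; every country appears
    at least once and extra records re-sample countries (multi-year
    observations). Anchors are calibrated on the drawn panel itself, as
    they would be on real baseline data. With ``residual_sd = (0, 0)``
    the panel lies exactly on the surface.
    """
    rng = np.random.default_rng(config.seed)
    n, nc = config.n_records, config.n_countries
    countries = [f"C{i + 1:03d}" for i in range(nc)]
    regions = {c: _region_name(i % config.n_regions) for i, c in enumerate(countries)}
    # every country once, remainder drawn with replacement (multi-year records)
    picks = list(range(nc)) + rng.integers(0, nc, size=n - nc).tolist()

    x = rng.uniform(*config.pou_range, size=n)
    gdp = np.exp(rng.uniform(*np.log(config.gdp_range), size=n))
    gini = rng.uniform(*config.gini_range, size=n)
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    pops = rng.uniform(*config.pop_range, size=n)

    anchors = calibrate_anchors(
        [CountryYearRecord("c", "r", 2000, 0, 0, 0, g, gi, 0) for g, gi in zip(gdp, gini)]
    )
    w = development_score(gdp, gini, anchors)

    p2, p3 = config.true_params.moderate, config.true_params.severe
    sd2, sd3 = config.residual_sd
    records = []
    for i in range(n):
        m2 = p2.alpha.value + p2.beta.central * x[i] + p2.gamma.value * w[i] + p2.theta.value * x[i] * w[i]
        m3 = p3.alpha.value + p3.beta.central * x[i] + p3.gamma.value * w[i] + p3.theta.value * x[i] * w[i]
        for attempt in range(MAX_RESAMPLE):
            y2 = m2 + (rng.normal(0.0, sd2) if sd2 > 0 else 0.0)
            y3 = m3 + (rng.normal(0.0, sd3) if sd3 > 0 else 0.0)
            if 0.0 <= y2 <= 1.0 and 0.0 <= y3 <= 1.0 and y2 + y3 <= 1.0:
                break
        else:
            raise RuntimeError(
                f"could not draw feasible stunting proportions at record {i} "
                f"(surface ({m2:.3f}, {m3:.3f}), noise {config.residual_sd}); "
                "the noise level is infeasible for truncation by resampling"
            )
        c = countries[picks[i]]
        records.append(CountryYearRecord(
            country_id=c, region_id=regions[c], year=int(years[i]),
            stunting_moderate=float(y2), stunting_severe=float(y3), pou=float(x[i]),
            gdp_pc=float(gdp[i]), gini=float(gini[i]), pop_u5=float(pops[i]),
        ))
    return records, GroundTruth(params=config.true_params, anchors=anchors)


class ScenarioTruth(NamedTuple):
    """Per-country generating values behind the scenario table."""

    regions: dict  # country -> region
    baseline_pou: dict  # country -> PoU at the no-shift calorie level
    baseline_des: dict  # country -> back-solved kcal/person/day


def generate_scenarios(
    config: SyntheticConfig,
    panel: Sequence[CountryYearRecord] | None = None,
) -> tuple[list[ScenarioInput], ScenarioTruth]:
    """Build a country × scenario input table consistent with a panel.

    Each country's baseline undernourishment (its most recent panel
    value, or a fresh draw if no panel is given) is converted to a
    baseline calorie availability by inverting the intake distribution;
    scenario calories apply the configured multiplicative shifts. GDP is
    projected by a per-region growth multiplier, identical across
    scenarios for within-scenario consistency; Gini, CV and MDER stay at
    baseline.
    """
    if panel is None:
        panel, _ = generate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5CE11]))

    latest: dict[str, CountryYearRecord] = {}
    for r in panel:
        if r.country_id not in latest or r.year > latest[r.country_id].year:
            latest[r.country_id] = r
    # keep low-income countries only: the projection focuses on regions
    # where development has not saturated (see module docstring)
    countries = sorted(c for c in latest if latest[c].gdp_pc <= config.scenario_gdp_max)
    if not countries:
        raise ValueError(
            f"no panel country has baseline GDP <= {config.scenario_gdp_max}; "
            "raise scenario_gdp_max or widen gdp_range"
        )
    regions = {c: latest[c].region_id for c in countries}
    region_growth = {
        reg: rng.uniform(*config.gdp_growth_range) for reg in sorted(set(regions.values()))
    }

    inputs: list[ScenarioInput] = []
    baseline_pou, baseline_des = {}, {}
    for c in countries:
        rec = latest[c]
        cv = float(rng.uniform(*config.cv_range))
        mder = float(rng.uniform(*config.mder_range))
        des0 = solve_des(rec.pou, cv, mder)
        baseline_pou[c], baseline_des[c] = rec.pou, des0
        gdp_proj = rec.gdp_pc * region_growth[regions[c]]
        pop_proj = float(rng.uniform(*config.pop_range))
        for scen, effect in config.scenario_effects.items():
            inputs.append(ScenarioInput(
                country_id=c, scenario_id=scen,
                kcal_pc_day=des0 * effect, gdp_pc_proj=gdp_proj,
                gini_baseline=rec.gini, cv_baseline=cv, mder=mder,
                pop_u5_proj=pop_proj,
            ))
    # sanity: the back-solved calories must reproduce the baseline PoU
    for s in inputs:
        if config.scenario_effects.get(s.scenario_id) == 1.0:
            assert abs(estimate_pou(s.kcal_pc_day, s.cv_baseline, s.mder)
                       - baseline_pou[s.country_id]) < 1e-6
    return inputs, ScenarioTruth(regions=regions, baseline_pou=baseline_pou, baseline_des=baseline_des)
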