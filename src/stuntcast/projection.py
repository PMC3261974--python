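"""Monte Carlo projection of stunting under scenario inputs.

Parameter uncertainty is propagated through the bilinear surface by
sampling: alpha, gamma and theta from normals centred on their point
estimates with their standard errors as spreads, and beta uniformly over
its plausible (1st–10th percentile) range. Each draw gives a stunting
proportion; draws are accepted only if strictly inside (0, 1), and
sampling continues until a target number of accepted draws (default
100,000) is reached. Rejections below 0 and above 1 are counted
separately — rejection truncates the distribution, so the counts are the
bias diagnostic (low-side rejection pushes the accepted mean up,
high-side down) and are always reported.

Country-level sample streams are combined into regional ones by
population-weighted averaging per draw index, and scenarios are compared
by the relative increase of the climate-scenario mean (averaged over the
two climate models) over the no-climate-change mean.

Reproducibility: every (country, scenario, level) stream gets its own
generator, deterministically derived from the master seed, so countries
are independent and a run is bit-reproducible regardless of ordering.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .development import DevelopmentAnchors, development_score
from .model import LevelParams, StuntingParams, LEVELS
from .panel import ScenarioInput
from .undernourishment import project_pou

logger = logging.getLogger(__name__)

__all__ = [
    "POU_FIT_MAX",
    "derive_seed",
    "sample_params",
    "simulate_country",
    "aggregate_region",
    "summarize",
    "relative_increase",
    "run_projection",
    "LevelSamples",
    "Summary",
    "RelativeIncrease",
    "ProjectionResult",
]

POU_FIT_MAX = 0.76  # largest undernourishment proportion in the calibration panel
N_SAMPLES_DEFAULT = 100_000
ACCEPTANCE_FLOOR = 0.01


def derive_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Deterministic per-stream seed from a master seed and string/int keys.

    Keys are hashed (CRC-32 of their string form), so the stream for a
    given (country, scenario, level) does not depend on iteration order.
    """
    entropy = [int(master_seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.SeedSequence(entropy)


class ParamDraw(NamedTuple):
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray


def sample_params(level_params: LevelParams, rng: np.random.Generator, size: int = 1) -> ParamDraw:
    """Draw (alpha, beta, gamma, theta) vectors for one stunting level.

    Normal draws for the regression parameters, uniform for beta over
    its plausible range. Zero standard errors and a collapsed beta range
    reproduce the point estimates exactly.
    """
    p = level_params
    return ParamDraw(
        alpha=rng.normal(p.alpha.value, p.alpha.se, size),
        beta=rng.uniform(p.beta.low, p.beta.high, size),
        gamma=rng.normal(p.gamma.value, p.gamma.se, size),
        theta=rng.normal(p.theta.value, p.theta.se, size),
    )


@dataclass(frozen=True)
class LevelSamples:
    """Accepted draws for one (country, scenario, level) stream."""

    samples: np.ndarray
    n_rejected_low: int  # draws <= 0
    n_rejected_high: int  # draws >= 1

    @property
    def n_drawn(self) -> int:
        return len(self.samples) + self.n_rejected_low + self.n_rejected_high

    @property
    def rejection_proportions(self) -> tuple[float, float]:
        n = self.n_drawn
        return self.n_rejected_low / n, self.n_rejected_high / n


def _simulate_level(level_params, x, w, n_target, rng, acceptance_floor, batch):
    accepted = []
    n_low = n_high = 0
    n_accepted = 0
    first_batch = True
    while n_accepted < n_target:
        d = sample_params(level_params, rng, batch)
        y = d.alpha + d.beta * x + d.gamma * w + d.theta * x * w
        ok = (y > 0.0) & (y < 1.0)
        if first_batch:
            rate = ok.mean()
            if rate < acceptance_floor:
                raise RuntimeError(
                    f"acceptance rate {rate:.4f} below floor {acceptance_floor} at "
                    f"(x={x}, w={w}) — the model is outside its fitted range"
                )
            first_batch = False
        need = n_target - n_accepted
        cum = np.cumsum(ok)
        if cum[-1] >= need:
            # stop at the draw that yields the final acceptance: the stream
            # is "the first n_target accepted", not a full extra batch
            stop = int(np.searchsorted(cum, need))
            y, ok = y[: stop + 1], ok[: stop + 1]
        accepted.append(y[ok])
        n_accepted += int(ok.sum())
        n_low += int((y <= 0.0).sum())
        n_high += int((y >= 1.0).sum())
    return LevelSamples(
        samples=np.concatenate(accepted)[:n_target],
        n_rejected_low=n_low,
        n_rejected_high=n_high,
    )


def simulate_country(
    params: StuntingParams,
    x: float,
    w: float,
    n_target: int = N_SAMPLES_DEFAULT,
    seed: int | np.random.SeedSequence = 0,
    acceptance_floor: float = ACCEPTANCE_FLOOR,
) -> dict[int, LevelSamples]:
    """Accepted-sample streams for one country at (x, w), per level.

    Levels are sampled independently (separate parameter draws). An
    acceptance rate below ``acceptance_floor`` on the first batch is
    fatal — it means essentially all the parameter mass maps outside
    (0, 1), i.e. the inputs are far outside the fitted range.
    """
    if not (0.0 <= x <= 1.0 and 0.0 <= w <= 1.0):
        raise ValueError(f"x and w must lie in [0, 1], got ({x}, {w})")
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    if x > POU_FIT_MAX:
        logger.warning(
            "undernourishment %.3f exceeds the calibration maximum %.2f; "
            "stunting estimates should be interpreted cautiously", x, POU_FIT_MAX,
        )
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    out = {}
    batch = max(min(n_target, 200_000), 10_000)
    # one child sequence per level, in fixed level order, so streams are
    # independent across levels yet bit-reproducible
    for k, child in zip(LEVELS, base.spawn(len(LEVELS))):
        rng = np.random.default_rng(child)
        out[k] = _simulate_level(params.level(k), x, w, n_target, rng, acceptance_floor, batch)
    return out


def aggregate_region(
    country_samples: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
) -> np.ndarray:
    """Population-weighted regional stream: weighted mean per draw index."""
    if not country_samples:
        raise ValueError("no country samples to aggregate")
    countries = list(country_samples)
    lengths = {len(country_samples[c]) for c in countries}
    if len(lengths) != 1:
        raise ValueError(f"mismatched sample counts across countries: {sorted(lengths)}")
    wts = np.array([weights[c] for c in countries], dtype=float)
    if np.any(wts <= 0):
        raise ValueError("weights must be positive")
    wts /= wts.sum()  # normalise first: a single country aggregates to itself exactly
    stack = np.stack([np.asarray(country_samples[c], dtype=float) for c in countries])
    return wts @ stack


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float  # sample SD, n-1 denominator
    percentiles: dict
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def summarize(
    samples: np.ndarray,
    percentiles: Sequence[float] = (2.5, 25.0, 50.0, 75.0, 97.5),
    n_bins: int = 50,
) -> Summary:
    """Mean, SD, percentile table and fixed-width histogram of a stream."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    hi = float(samples.max())
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    counts, edges = np.histogram(samples, bins=edges)
    return Summary(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        percentiles={p: float(v) for p, v in zip(percentiles, np.percentile(samples, percentiles))},
        bin_edges=edges,
        bin_counts=counts,
    )


class RelativeIncrease(NamedTuple):
    value: float  # unrounded percent
    rounded: int | None  # half-up to the nearest integer, for reporting


def relative_increase(mean_nocc: float, mean_scenario_a: float, mean_scenario_b: float) -> RelativeIncrease:
    """Percent increase of the average climate-scenario mean over no-CC.

    ``100 * ((a + b) / 2 / mean_nocc - 1)``; the rounded value (half-up)
    is for report tables, the unrounded one is retained because rounding
    the inputs first can shift the printed percent by a point.
    """
    if mean_nocc == 0:
        logger.warning("no-climate-change mean is zero; relative increase undefined")
        return RelativeIncrease(float("nan"), None)
    v = 100.0 * ((mean_scenario_a + mean_scenario_b) / 2.0 / mean_nocc - 1.0)
    return RelativeIncrease(v, int(math.floor(v + 0.5)))


@dataclass
class ProjectionResult:
    """Everything a projection run produces.

    ``country`` rows carry the scenario inputs' derived (x, w), the
    per-level accepted-sample means/SDs and rejection proportions;
    ``regional`` rows the population-weighted aggregates; ``increases``
    the scenario-comparison percents (stunting levels and PoU).
    ``regional_samples`` maps (region, scenario, level) to the full
    aggregated stream for histogramming.
    """

    country: pd.DataFrame
    regional: pd.DataFrame
    increases: pd.DataFrame
    regional_samples: dict = field(default_factory=dict)
    country_samples: dict = field(default_factory=dict)


def run_projection(
    params: StuntingParams,
    scenarios: Sequence[ScenarioInput],
    regions: Mapping[str, str],
    anchors: DevelopmentAnchors,
    n_samples: int = N_SAMPLES_DEFAULT,
    seed: int = 0,
    reference_scenario: str = "noCC",
) -> ProjectionResult:
    """Project stunting for every scenario input and aggregate by region.

    For each country × scenario: PoU from scenario calories (baseline CV
    and MDER), development score from projected GDP and baseline Gini,
    then the Monte Carlo engine. Regional streams are population-weighted
    (projected under-5 population) per draw; relative increases compare
    each non-reference scenario pair against ``reference_scenario``.
    """
    scen_ids = sorted({s.scenario_id for s in scenarios})
    country_rows = []
    country_samples = {}
    pou_by = {}
    for s in scenarios:
        x = project_pou(s)
        w = development_score(s.gdp_pc_proj, s.gini_baseline, anchors)
        pou_by[(s.country_id, s.scenario_id)] = x
        sims = simulate_country(
            params, x, w, n_target=n_samples,
            seed=derive_seed(seed, s.country_id, s.scenario_id),
        )
        for k, ls in sims.items():
            country_samples[(s.country_id, s.scenario_id, k)] = ls
            p_low, p_high = ls.rejection_proportions
            country_rows.append({
                "country_id": s.country_id, "region_id": regions[s.country_id],
                "scenario_id": s.scenario_id, "level": k, "pou": x, "dev_score": w,
                "mean": float(ls.samples.mean()), "sd": float(ls.samples.std(ddof=1)),
                "prop_rejected_low": p_low, "prop_rejected_high": p_high,
                "pop_u5_proj": s.pop_u5_proj,
            })
    country = pd.DataFrame(country_rows)

    weights = {s.country_id: s.pop_u5_proj for s in scenarios}
    regional_rows, regional_samples = [], {}
    for region in sorted(set(regions[s.country_id] for s in scenarios)):
        members = sorted({s.country_id for s in scenarios if regions[s.country_id] == region})
        for scen in scen_ids:
            pou_reg = float(np.average(
                [pou_by[(c, scen)] for c in members],
                weights=[weights[c] for c in members],
            ))
            for k in LEVELS:
                agg = aggregate_region(
                    {c: country_samples[(c, scen, k)].samples for c in members}, weights,
                )
                regional_samples[(region, scen, k)] = agg
                n_low = sum(country_samples[(c, scen, k)].n_rejected_low for c in members)
                n_high = sum(country_samples[(c, scen, k)].n_rejected_high for c in members)
                n_drawn = sum(country_samples[(c, scen, k)].n_drawn for c in members)
                regional_rows.append({
                    "region_id": region, "scenario_id": scen, "level": k,
                    "pou": pou_reg,
                    "mean": float(agg.mean()), "sd": float(agg.std(ddof=1)),
                    "prop_rejected_low": n_low / n_drawn,
                    "prop_rejected_high": n_high / n_drawn,
                })
    regional = pd.DataFrame(regional_rows)

    increases = _increase_table(regional, reference_scenario)
    return ProjectionResult(
        country=country, regional=regional, increases=increases,
        regional_samples=regional_samples, country_samples=country_samples,
    )


def saturation_sensitivity_report(
    params: StuntingParams,
    scenarios: Sequence[ScenarioInput],
    regions: Mapping[str, str],
    panel: Sequence,
    anchors: DevelopmentAnchors,
    n_samples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Regional means with and without the development-score saturation.

    Reruns the projection with the fixed $10,000/0.38 saturation point
    replaced by the best adjusted income observed in the baseline panel,
    and tabulates both sets of regional means side by side. This is a
    comparison report for judging how much the saturation assumption
    moves the estimates, not a pass/fail check.
    """
    from .development import unsaturated_anchors

    base = run_projection(params, scenarios, regions, anchors,
                          n_samples=n_samples, seed=seed)
    alt = run_projection(params, scenarios, regions, unsaturated_anchors(panel, anchors),
                         n_samples=n_samples, seed=seed)
    keys = ["region_id", "scenario_id", "level"]
    merged = base.regional[keys + ["mean"]].merge(
        alt.regional[keys + ["mean"]], on=keys, suffixes=("_saturated", "_unsaturated"),
    )
    merged["difference"] = merged["mean_unsaturated"] - merged["mean_saturated"]
    return merged


def _increase_table(regional: pd.DataFrame, reference: str) -> pd.DataFrame:
    scen_ids = sorted(regional["scenario_id"].unique())
    if reference not in scen_ids:
        logger.warning("reference scenario %r absent; no increase table", reference)
        return pd.DataFrame()
    others = [s for s in scen_ids if s != reference]
    rows = []
    for region, grp in regional.groupby("region_id"):
        # stunting levels from the Monte Carlo means, PoU from the weighted PoU column
        for quantity, col in (("stunting", "mean"), ("pou", "pou")):
            levels = LEVELS if quantity == "stunting" else (None,)
            for k in levels:
                sub = grp if k is None else grp[grp["level"] == k]
                ref = float(sub.loc[sub["scenario_id"] == reference, col].iloc[0])
                means = [float(sub.loc[sub["scenario_id"] == s, col].iloc[0]) for s in others]
                if len(means) == 2:
                    ri = relative_increase(ref, means[0], means[1])
                elif ref == 0:
                    ri = RelativeIncrease(float("nan"), None)
                else:
                    v = 100.0 * (float(np.mean(means)) / ref - 1.0)
                    ri = RelativeIncrease(v, int(math.floor(v + 0.5)))
                rows.append({
                    "region_id": region, "quantity": quantity, "level": k,
                    "relative_increase_pct": ri.value, "rounded": ri.rounded,
                })
    return pd.DataFrame(rows)
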