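"""The bilinear stunting model and its two-step attribution fit.

Stunting prevalence at level k (2 = moderate, 3 = severe) in a country
is modelled as

    y_k = alpha_k + beta_k * x + gamma_k * w + theta_k * x * w

with x the proportion undernourished (food causes), w the development
score (nonfood causes), and their product the interaction; no/mild
stunting is the complement y_1 = 1 - y_2 - y_3.

Fitting is deliberately theory-driven rather than statistical, in two
steps. First, beta_k — the assumed physiological link between a lack of
food and stunting, taken to be globally stable — is estimated from the
distribution of observed ratios y_k / x: conceptually its minimum over
the panel, in practice a low percentile (5th, with the 1st and 10th as
the plausible range) to guard against data errors. beta is estimated on
the full panel, before any validation split. Second, the food-attributable
share r = beta_k * x is removed and the residual s = y - r (nonfood plus
interaction) is regressed on (1, w, x*w) by ordinary least squares,
separately per level, yielding alpha_k, gamma_k, theta_k with standard
errors. Negative residuals are retained — truncating them would bias the
fit. Collinearity between x and x*w is accepted as an approximation; the
design's condition number is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .development import DevelopmentAnchors, calibrate_anchors, development_score
from .panel import CountryYearRecord, split_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "BetaEstimate",
    "ValueSE",
    "LevelParams",
    "StuntingParams",
    "FoodAttribution",
    "RatioDistribution",
    "ValidationReport",
    "default_params",
    "ratio_distribution",
    "estimate_beta",
    "attribute_food",
    "residual_nonfood",
    "fit_nonfood",
    "predict_stunting",
    "validate_model",
    "fit_model",
]

LEVELS = (2, 3)  # moderate, severe
DEFAULT_PERCENTILES = (1.0, 5.0, 10.0)


class ValueSE(NamedTuple):
    """A point estimate with its standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class BetaEstimate:
    """Physiological food→stunting coefficient with its plausible range.

    ``central`` is the chosen low percentile of the y/x ratio
    distribution; ``low``/``high`` bound the plausible range (used as
    uniform bounds in projection).
    """

    level: int
    central: float
    low: float
    high: float
    n_ratios: int
    n_excluded: int = 0  # records dropped for x == 0

    def __post_init__(self):
        if not 0 < self.low <= self.central <= self.high:
            raise ValueError(
                f"beta estimates must satisfy 0 < low <= central <= high, "
                f"got ({self.low}, {self.central}, {self.high})"
            )


@dataclass(frozen=True)
class LevelParams:
    """Full parameter set for one stunting level."""

    level: int
    beta: BetaEstimate
    alpha: ValueSE
    gamma: ValueSE
    theta: ValueSE
    n_fit: int = 0
    resid_var: float = float("nan")

    def __post_init__(self):
        for name in ("alpha", "gamma", "theta"):
            if getattr(self, name).se < 0:
                raise ValueError(f"{name} standard error is negative")


@dataclass(frozen=True)
class StuntingParams:
    """Model parameters for both modelled levels (moderate and severe)."""

    moderate: LevelParams
    severe: LevelParams

    def level(self, k: int) -> LevelParams:
        if k == 2:
            return self.moderate
        if k == 3:
            return self.severe
        raise KeyError(f"no parameters for level {k} (levels are 2 and 3)")

    def to_dict(self) -> dict:
        return {"moderate": asdict(self.moderate), "severe": asdict(self.severe)}

    @classmethod
    def from_dict(cls, d: dict) -> "StuntingParams":
        def lvl(x):
            return LevelParams(
                level=x["level"],
                beta=BetaEstimate(**x["beta"]),
                alpha=ValueSE(*x["alpha"]),
                gamma=ValueSE(*x["gamma"]),
                theta=ValueSE(*x["theta"]),
                n_fit=x.get("n_fit", 0),
                resid_var=x.get("resid_var", float("nan")),
            )
        return cls(moderate=lvl(d["moderate"]), severe=lvl(d["severe"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StuntingParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_params() -> StuntingParams:
    """Default parameters from the original global country-panel calibration.

    beta is quoted as the 5th percentile with a 1st–10th percentile
    plausible range; alpha, gamma and theta carry OLS standard errors.
    """
    return StuntingParams(
        moderate=LevelParams(
            level=2,
            beta=BetaEstimate(level=2, central=0.35, low=0.20, high=0.44, n_ratios=186),
            alpha=ValueSE(0.025, 0.013),
            gamma=ValueSE(0.26, 0.028),
            theta=ValueSE(-0.43, 0.041),
            n_fit=149,
        ),
        severe=LevelParams(
            level=3,
            beta=BetaEstimate(level=3, central=0.18, low=0.11, high=0.28, n_ratios=186),
            alpha=ValueSE(-0.052, 0.021),
            gamma=ValueSE(0.34, 0.044),
            theta=ValueSE(-0.18, 0.064),
            n_fit=149,
        ),
    )


class RatioDistribution(NamedTuple):
    ratios: np.ndarray  # ascending
    n_excluded: int  # records with x == 0


def ratio_distribution(panel: Sequence[CountryYearRecord], level: int) -> RatioDistribution:
    """Ascending distribution of y_k / x across the panel.

    Records with zero undernourishment are excluded (the ratio is
    undefined) and counted.
    """
    if not panel:
        raise ValueError("panel is empty")
    if level not in LEVELS:
        raise ValueError(f"level must be 2 or 3, got {level}")
    attr = "stunting_moderate" if level == 2 else "stunting_severe"
    y = np.array([getattr(r, attr) for r in panel], dtype=float)
    x = np.array([r.pou for r in panel], dtype=float)
    keep = x > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("every record has zero undernourishment; no ratios defined")
    return RatioDistribution(np.sort(y[keep] / x[keep]), n_excluded)


def estimate_beta(
    ratios: RatioDistribution | np.ndarray,
    level: int,
    percentiles: tuple[float, float, float] = DEFAULT_PERCENTILES,
) -> BetaEstimate:
    """Estimate beta_k from the ratio distribution.

    The central value is the middle percentile (default 5th); the outer
    two (default 1st and 10th) bound its plausible range. Percentiles
    use linear interpolation between closest order statistics
    (``numpy.percentile`` method ``"linear"``). With percentiles
    (0, 0, 0) this degenerates to the pure minimum-ratio estimator.
    """
    n_excluded = 0
    if isinstance(ratios, RatioDistribution):
        ratios, n_excluded = ratios
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 ratios to estimate beta")
    p_low, p_central, p_high = percentiles
    if not 0 <= p_low <= p_central <= p_high < 100:
        raise ValueError(f"percentiles must be ordered within [0, 100), got {percentiles}")
    low, central, high = np.percentile(ratios, [p_low, p_central, p_high], method="linear")
    return BetaEstimate(
        level=level, central=float(central), low=float(low), high=float(high),
        n_ratios=int(ratios.size), n_excluded=n_excluded,
    )


def attribute_food(beta_central: float, x):
    """Food-attributable stunting r = beta * x."""
    if not beta_central > 0:
        raise ValueError(f"beta must be positive, got {beta_central}")
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0) | (x_arr > 1)):
        raise ValueError("undernourishment proportion must lie in [0, 1]")
    r = beta_central * x_arr
    return float(r) if r.ndim == 0 else r


def residual_nonfood(y, r):
    """Nonfood + interaction residual s = y - r.

    May be negative when beta * x exceeds observed stunting; negatives
    are retained (and logged by the fitting step), never truncated.
    """
    s = np.asarray(y, dtype=float) - np.asarray(r, dtype=float)
    return float(s) if s.ndim == 0 else s


class FoodAttribution(NamedTuple):
    """Stunting split into food-attributable and residual parts; r + s = y."""

    r: float
    s: float


def attribute(beta_central: float, x: float, y: float) -> FoodAttribution:
    r = attribute_food(beta_central, x)
    return FoodAttribution(r=r, s=residual_nonfood(y, r))


def _level_arrays(panel, level):
    attr = "stunting_moderate" if level == 2 else "stunting_severe"
    y = np.array([getattr(r, attr) for r in panel], dtype=float)
    x = np.array([r.pou for r in panel], dtype=float)
    return y, x


def fit_nonfood(
    train: Sequence[CountryYearRecord],
    beta_moderate: BetaEstimate,
    beta_severe: BetaEstimate,
    anchors: DevelopmentAnchors,
) -> StuntingParams:
    """Second fitting step: OLS of the nonfood residual on (1, w, x*w).

    For each level, the food share beta*x is subtracted from observed
    stunting and the residual is regressed on an intercept, the
    development score and the interaction term, giving alpha, gamma and
    theta with standard errors. The betas pass through unchanged —
    they were fitted first, and the stepwise order is the point.
    """
    if len(train) <= 3:
        raise ValueError("need more than 3 training records")
    gdp = np.array([r.gdp_pc for r in train], dtype=float)
    gini = np.array([r.gini for r in train], dtype=float)
    w = development_score(gdp, gini, anchors)

    levels = {}
    for level, beta in ((2, beta_moderate), (3, beta_severe)):
        y, x = _level_arrays(train, level)
        s = residual_nonfood(y, attribute_food(beta.central, x))
        n_neg = int((s < 0).sum())
        if n_neg:
            logger.info("level %d: %d negative nonfood residual(s) retained", level, n_neg)
        X = np.column_stack([np.ones_like(w), w, x * w])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError(
                f"level {level}: design matrix (1, w, x*w) is rank deficient — "
                "the development score or interaction is constant across the panel"
            )
        res = sm.OLS(s, X).fit()
        logger.info("level %d: design condition number %.3g", level, res.condition_number)
        levels[level] = LevelParams(
            level=level,
            beta=beta,
            alpha=ValueSE(float(res.params[0]), float(res.bse[0])),
            gamma=ValueSE(float(res.params[1]), float(res.bse[1])),
            theta=ValueSE(float(res.params[2]), float(res.bse[2])),
            n_fit=int(res.nobs),
            resid_var=float(res.mse_resid),
        )
    return StuntingParams(moderate=levels[2], severe=levels[3])


def predict_stunting(params: StuntingParams, x: float, w: float) -> tuple[float, float, float]:
    """Predicted (y1, y2, y3) at undernourishment x and development score w.

    Evaluates the bilinear surface with the central betas; y1 is the
    complement, so the three always sum to 1 exactly. No clamping here —
    out-of-range handling belongs to the Monte Carlo engine.
    """
    ys = {}
    for k in LEVELS:
        p = params.level(k)
        ys[k] = p.alpha.value + p.beta.central * x + p.gamma.value * w + p.theta.value * x * w
    y1 = 1.0 - ys[2] - ys[3]
    return y1, ys[2], ys[3]


@dataclass(frozen=True)
class ValidationReport:
    """Holdout predicted-vs-observed correlations, one per stunting level."""

    corr: dict  # level (1, 2, 3) -> Pearson r, or nan if undefined
    undefined: tuple  # levels where a zero-variance side made r undefined
    scatter: pd.DataFrame  # observed/predicted pairs for plotting


def validate_model(
    params: StuntingParams,
    holdout: Sequence[CountryYearRecord],
    anchors: DevelopmentAnchors,
) -> ValidationReport:
    """Correlate model predictions with observed stunting on a holdout.

    Each holdout record is predicted from its own (x, w); the report
    carries Pearson correlations per level (no/mild stunting observed
    as the complement of the two observed levels) and the scatter pairs.
    """
    if len(holdout) < 3:
        raise ValueError("need at least 3 holdout records")
    rows = []
    for r in holdout:
        w = development_score(r.gdp_pc, r.gini, anchors)
        y1p, y2p, y3p = predict_stunting(params, r.pou, w)
        rows.append({
            "country_id": r.country_id, "year": r.year,
            "obs_1": 1.0 - r.stunting_moderate - r.stunting_severe,
            "obs_2": r.stunting_moderate, "obs_3": r.stunting_severe,
            "pred_1": y1p, "pred_2": y2p, "pred_3": y3p,
        })
    scatter = pd.DataFrame(rows)
    corr, undefined = {}, []
    for k in (1, 2, 3):
        obs = scatter[f"obs_{k}"].to_numpy()
        pred = scatter[f"pred_{k}"].to_numpy()
        if np.std(obs) == 0 or np.std(pred) == 0:
            corr[k] = float("nan")
            undefined.append(k)
            logger.warning("level %d: zero variance, correlation undefined", k)
        else:
            corr[k] = float(np.corrcoef(obs, pred)[0, 1])
    return ValidationReport(corr=corr, undefined=tuple(undefined), scatter=scatter)


class FitResult(NamedTuple):
    params: StuntingParams
    anchors: DevelopmentAnchors
    validation: ValidationReport


def fit_model(
    panel: Sequence[CountryYearRecord],
    holdout_fraction: float = 0.2,
    seed: int = 0,
    percentiles: tuple[float, float, float] = DEFAULT_PERCENTILES,
) -> FitResult:
    """Run the full fitting pipeline on a panel.

    Betas are estimated on the *entire* panel; the panel is then split,
    anchors are calibrated on the full baseline panel, the nonfood
    regression is fitted on the training part, and the model is
    validated on the holdout.
    """
    betas = {
        k: estimate_beta(ratio_distribution(panel, k), k, percentiles) for k in LEVELS
    }
    train, holdout = split_dataset(panel, holdout_fraction, seed)
    anchors = calibrate_anchors(panel)
    params = fit_nonfood(train, betas[2], betas[3], anchors)
    validation = validate_model(params, holdout, anchors)
    return FitResult(params=params, anchors=anchors, validation=validation)
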