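"""Country-year panel and scenario-table I/O.

The panel is the merged national dataset the stunting model is calibrated
on: one row per country-year with observed moderate/severe stunting
prevalence in under-fives, the FAO prevalence of undernourishment (PoU),
per capita GDP (2000 US$), the Gini coefficient, and the under-5
population. Countries appear once per survey year, so a country may
contribute several rows; no deduplication is performed.

All proportions are held internally on the [0, 1] scale. Columns supplied
as percentages (any value > 1 with the whole column ≤ 100) are detected
and rescaled with a warning, since both conventions occur in the source
databases. Rows failing validation are excluded and logged with the
reason, never repaired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountryYearRecord",
    "ScenarioInput",
    "PanelLoadResult",
    "ScenarioLoadResult",
    "load_panel",
    "write_panel",
    "panel_frame",
    "load_scenarios",
    "write_scenarios",
    "split_dataset",
]


@dataclass(frozen=True)
class CountryYearRecord:
    """One country-year observation of stunting and its candidate drivers."""

    country_id: str
    region_id: str
    year: int
    stunting_moderate: float  # proportion of under-5s > 2 SD below reference height-for-age
    stunting_severe: float  # proportion > 3 SD below
    pou: float  # prevalence of undernourishment, proportion
    gdp_pc: float  # per capita GDP, 2000 US$
    gini: float  # income Gini coefficient in [0, 1]
    pop_u5: float  # under-5 population

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        v: list[str] = []
        for name in ("stunting_moderate", "stunting_severe", "pou", "gini"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                v.append(f"{name}={val!r} outside [0, 1]")
        if self.stunting_moderate + self.stunting_severe > 1.0 + 1e-12:
            v.append("stunting_moderate + stunting_severe > 1")
        if not self.gdp_pc > 0:
            v.append(f"gdp_pc={self.gdp_pc!r} not positive")
        if not 1900 <= self.year <= 2100:
            v.append(f"year={self.year!r} outside [1900, 2100]")
        if self.pop_u5 < 0:
            v.append(f"pop_u5={self.pop_u5!r} negative")
        return v


@dataclass(frozen=True)
class ScenarioInput:
    """Per country × scenario inputs for a projection run.

    ``kcal_pc_day`` is the scenario's per capita dietary energy supply;
    ``cv_baseline`` and ``mder`` are the baseline intake-distribution
    coefficient of variation and minimum dietary energy requirement, held
    at baseline in every scenario because no projections of them exist.
    """

    country_id: str
    scenario_id: str  # e.g. "noCC", "NCAR", "CSIRO", or user-defined
    kcal_pc_day: float
    gdp_pc_proj: float
    gini_baseline: float
    cv_baseline: float
    mder: float
    pop_u5_proj: float

    def violations(self) -> list[str]:
        v: list[str] = []
        if not self.kcal_pc_day > 0:
            v.append(f"kcal_pc_day={self.kcal_pc_day!r} not positive")
        if not self.mder > 0:
            v.append(f"mder={self.mder!r} not positive")
        if not 0.0 < self.cv_baseline < 1.0:
            v.append(f"cv_baseline={self.cv_baseline!r} outside (0, 1)")
        if not self.gdp_pc_proj > 0:
            v.append(f"gdp_pc_proj={self.gdp_pc_proj!r} not positive")
        if not 0.0 <= self.gini_baseline < 1.0:
            v.append(f"gini_baseline={self.gini_baseline!r} outside [0, 1)")
        if self.pop_u5_proj < 0:
            v.append(f"pop_u5_proj={self.pop_u5_proj!r} negative")
        return v


PANEL_FIELDS = tuple(f.name for f in dc_fields(CountryYearRecord))
SCENARIO_FIELDS = tuple(f.name for f in dc_fields(ScenarioInput))

# columns eligible for percent → proportion auto-rescaling
_PANEL_PROPORTION_COLS = ("stunting_moderate", "stunting_severe", "pou", "gini")
_SCENARIO_PROPORTION_COLS = ("gini_baseline", "cv_baseline")


class PanelLoadResult(NamedTuple):
    records: list[CountryYearRecord]
    exclusions: list[tuple[int, str]]  # (0-based row index, reason)


class ScenarioLoadResult(NamedTuple):
    records: list[ScenarioInput]
    exclusions: list[tuple[int, str]]


def _read_table(path, fields: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    schema = dict(schema or {})
    # round_trip parsing: the default float parser can be off by one ulp,
    # which would break lossless write -> read round-trips
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for field in fields:
        col = schema.get(field, field)
        if col not in df.columns:
            raise ValueError(f"required column {col!r} (field {field!r}) missing from {path}")
        rename[col] = field
    return df.rename(columns=rename)[list(fields)]


def _rescale_percent_columns(df: pd.DataFrame, cols: Iterable[str], source: str) -> None:
    # A column is on the percent scale when most of its values exceed 1 and
    # none exceed 100; a lone value just above 1 in an otherwise [0, 1]
    # column is an error for validation to catch, not a unit mismatch.
    for col in cols:
        vals = df[col].dropna()
        if len(vals) and vals.max() <= 100.0 and (vals > 1.0).mean() > 0.5:
            logger.warning(
                "column %r in %s looks like percentages (max %.3g); dividing by 100",
                col, source, vals.max(),
            )
            df[col] = df[col] / 100.0


def _load(path, cls, fields, prop_cols, schema):
    df = _read_table(path, fields, schema)
    _rescale_percent_columns(df, prop_cols, str(path))
    records, exclusions = [], []
    n_missing = 0
    for idx, row in df.iterrows():
        missing = [f for f in fields if pd.isna(row[f])]
        if missing:
            n_missing += 1
            reason = f"missing value(s) in {', '.join(missing)}"
            exclusions.append((int(idx), reason))
            logger.info("row %d excluded: %s", idx, reason)
            continue
        kwargs = {f: row[f] for f in fields}
        for f in ("country_id", "region_id", "scenario_id"):
            if f in kwargs:
                kwargs[f] = str(kwargs[f])
        if "year" in kwargs:
            kwargs["year"] = int(kwargs["year"])
        rec = cls(**kwargs)
        bad = rec.violations()
        if bad:
            reason = "; ".join(bad)
            exclusions.append((int(idx), reason))
            logger.info("row %d excluded: %s", idx, reason)
            continue
        records.append(rec)
    if n_missing:
        logger.warning("%d row(s) with missing fields excluded from %s", n_missing, path)
    return records, exclusions


def load_panel(path, schema: Mapping[str, str] | None = None) -> PanelLoadResult:
    """Read a country-year panel CSV.

    Parameters
    ----------
    path : file path
        CSV with a header row.
    schema : mapping, optional
        Maps internal field names to the file's column names, for files
        whose headers differ from the defaults (the field names).

    Returns
    -------
    PanelLoadResult
        Valid records in file order, plus ``(row, reason)`` exclusions
        for rows with missing fields or invariant violations.
    """
    records, exclusions = _load(path, CountryYearRecord, PANEL_FIELDS, _PANEL_PROPORTION_COLS, schema)
    return PanelLoadResult(records, exclusions)


def load_scenarios(path, schema: Mapping[str, str] | None = None) -> ScenarioLoadResult:
    """Read a country × scenario input CSV (see :class:`ScenarioInput`)."""
    records, exclusions = _load(path, ScenarioInput, SCENARIO_FIELDS, _SCENARIO_PROPORTION_COLS, schema)
    return ScenarioLoadResult(records, exclusions)


def panel_frame(records: Sequence[CountryYearRecord]) -> pd.DataFrame:
    """Panel records as a DataFrame (columns = field names, file order)."""
    return pd.DataFrame([vars(r) for r in records], columns=list(PANEL_FIELDS))


def write_panel(records: Sequence[CountryYearRecord], path) -> None:
    # %.17g keeps doubles exact so write -> read round-trips losslessly
    panel_frame(records).to_csv(path, index=False, float_format="%.17g")


def write_scenarios(records: Sequence[ScenarioInput], path) -> None:
    pd.DataFrame(
        [vars(r) for r in records], columns=list(SCENARIO_FIELDS)
    ).to_csv(path, index=False, float_format="%.17g")


def split_dataset(
    panel: Sequence[CountryYearRecord],
    holdout_fraction: float,
    seed: int,
) -> tuple[list[CountryYearRecord], list[CountryYearRecord]]:
    """Randomly partition the panel into training and validation subsets.

    The holdout size is ``round_half_up(holdout_fraction * n)``, so a
    186-record panel at fraction 0.2 reserves exactly 37 records. The
    partition is deterministic for a fixed seed, and each subset keeps
    the original row order.

    Returns ``(train, holdout)``.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    if not panel:
        raise ValueError("panel is empty")
    n = len(panel)
    n_holdout = int(math.floor(holdout_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    holdout_idx = set(perm[:n_holdout].tolist())
    holdout = [panel[i] for i in range(n) if i in holdout_idx]
    train = [panel[i] for i in range(n) if i not in holdout_idx]
    return train, holdout
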