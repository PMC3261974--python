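import pytest

from stuntcast.model import (
    BetaEstimate,
    LevelParams,
    StuntingParams,
    ValueSE,
    default_params,
)
from stuntcast.synthetic import SyntheticConfig, generate_panel, generate_scenarios


@pytest.fixture(scope="session")
def default_panel():
    """Default-condition synthetic panel (186 records) with its ground truth."""
    return generate_panel(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_panel():
    """Panel lying exactly on the generating surface (zero residual noise)."""
    return generate_panel(SyntheticConfig(seed=11, residual_sd=(0.0, 0.0)))


@pytest.fixture(scope="session")
def default_scenarios(default_panel):
    records, _ = default_panel
    return generate_scenarios(SyntheticConfig(seed=7), records)


@pytest.fixture(scope="session")
def table_params():
    """The published central parameters with their uncertainty."""
    return default_params()


def degenerate(params: StuntingParams) -> StuntingParams:
    """Collapse all parameter uncertainty: SEs to 0, beta range to its centre."""

    def collapse(p: LevelParams) -> LevelParams:
        b = p.beta
        return LevelParams(
            level=p.level,
            beta=BetaEstimate(level=b.level, central=b.central, low=b.central,
                              high=b.central, n_ratios=b.n_ratios),
            alpha=ValueSE(p.alpha.value, 0.0),
            gamma=ValueSE(p.gamma.value, 0.0),
            theta=ValueSE(p.theta.value, 0.0),
        )

    return StuntingParams(moderate=collapse(params.moderate), severe=collapse(params.severe))


@pytest.fixture()
def degenerate_params(table_params):
    return degenerate(table_params)
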