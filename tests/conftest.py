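import pandas as pd
import pytest

from ss2emu import (
    MethodRegistry,
    PopulationSeries,
    ServiceStatisticsTable,
    load_registry,
)


@pytest.fixture(scope="session")
def registry() -> MethodRegistry:
    return load_registry()


@pytest.fixture(scope="session")
def iud_curve(registry):
    return registry["iud_copper_t"].continuation


@pytest.fixture
def simple_stats() -> ServiceStatisticsTable:
    """100 Copper-T insertions in 2020, observed through 2022."""
    return ServiceStatisticsTable(
        pd.DataFrame(
            {
                "year": [2020, 2021, 2022],
                "method": ["iud_copper_t"] * 3,
                "ss_type": ["commodities_clients"] * 3,
                "count": [100.0, 0.0, 0.0],
            }
        )
    )


@pytest.fixture
def flat_population() -> PopulationSeries:
    return PopulationSeries(
        pd.DataFrame({"year": range(2015, 2031), "wra": [1_000_000.0] * 16})
    )
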