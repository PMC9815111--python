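import numpy as np
import pandas as pd
import pytest

from glycanclock import (
    GlycanPeakTable,
    SimulationConfig,
    simulate_ace_phenotype,
    simulate_twin_cohort,
)


@pytest.fixture(scope="session")
def small_ace_data():
    """200-pair twin dataset with a known A/C/E split."""
    return simulate_ace_phenotype(
        n_mz=80, n_dz=120, a2=0.4, c2=0.35, e2=0.25, mean=1.5, seed=7
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default cross-sectional cohort (479 MZ + 1193 DZ pairs)."""
    return simulate_twin_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def random_percent_table():
    rng = np.random.default_rng(5)
    vals = rng.dirichlet(np.full(8, 10.0), size=30) * 100.0
    df = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(30)],
        columns=[f"GP{i + 1}" for i in range(8)],
    )
    return GlycanPeakTable(df, scale="percent")
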