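import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rhizoq.io import CountTable, IndicatorTable
from rhizoq.simulate import SyntheticConfig, generate_experiment

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic pot experiment at the default design (2×5×3)."""
    return generate_experiment(SyntheticConfig(seed=7))


@pytest.fixture()
def small_indicator_table():
    """Tiny single-species indicator table: 2 doses × 3 replicates."""
    rng = np.random.default_rng(42)
    rows = []
    for di, dose in enumerate([0.0, 9.0]):
        for rep in range(1, 4):
            rows.append(
                {
                    "sample_id": f"P1S{di + 1}R{rep}",
                    "species": "P1",
                    "dose_pct": dose,
                    "replicate": rep,
                    "pH": 8.2 + 0.1 * dose / 9 + rng.normal(0, 0.02),
                    "EC": 150 + 10 * dose / 9 + rng.normal(0, 1),
                    "SOM": 21 + 15 * dose / 9 + rng.normal(0, 0.5),
                    "SAN": 20 + 30 * dose / 9 + rng.normal(0, 1),
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return IndicatorTable(df)


@pytest.fixture()
def toy_counts():
    """3 samples × 4 taxa toy count table."""
    return CountTable(
        pd.DataFrame(
            [[5, 3, 1, 1], [10, 0, 0, 0], [2, 2, 2, 2]],
            index=["s1", "s2", "s3"],
            columns=["tA", "tB", "tC", "tD"],
        )
    )
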