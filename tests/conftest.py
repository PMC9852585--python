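import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proxygwas.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Shared mid-small cohort: 3,000 individuals, 60 variants, 3 causal."""
    cfg = SimulationConfig(n_total=3000, n_measured=400, m_variants=60,
                           n_causal=3, n_replication=600, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_cohort():
    """Deterministic 8-row cohort for exact-arithmetic imputation checks."""
    from proxygwas.simulate import Cohort

    height = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5])
    table = pd.DataFrame({
        "iid": [f"i{k}" for k in range(8)],
        "sex": ["F"] * 8,
        "height": height,
        "weight": np.array([2.0, 1.0, 4.0, 3.0, 2.5, 1.5, 4.5, 3.5]),
        "fat": 2.0 * height + 3.0,
        "measured": [True] * 8,
    })
    return Cohort(table=table, proxy_cols=["height", "weight"],
                  target_cols=["fat"], covariate_cols=[])
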