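import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic two-cohort study shared across tests."""
    from psascreen import GeneratorConfig, generate_study

    cfg = GeneratorConfig(
        nhanes_sizes={"pso": 120, "psa": 40},
        chinese_sizes={"pso": 40, "psa": 15},
        screening_aux=True,
        seed=7,
    )
    return generate_study(cfg)


@pytest.fixture
def toy_cohort():
    """Tiny hand-written cohort table with known values."""
    return pd.DataFrame({
        "subject_id": ["s1", "s2", "s3", "s4"],
        "label": [0, 0, 1, 1],
        "crp": [0.4, 1.0, 4.0, 6.5],
        "lymphocyte_pct": [30.0, 25.0, 28.0, 33.0],
        "neutrophil_count": [4.0, 5.0, 4.4, 3.2],
        "eosinophil_count": [0.2, 0.3, 0.15, 0.1],
    })
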