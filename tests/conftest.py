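import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from neurocoex.simulate import ModuleSpec, SimCohortConfig, gen_brain_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Canonical case/control cohort: 3 planted modules (one destroyed in
    cases), pH covariate, 29 cases + 30 controls."""
    cfg = SimCohortConfig(
        n_genes=300,
        module_specs=[
            ModuleSpec(40, 0.9, True),
            ModuleSpec(30, 0.9, True),
            ModuleSpec(20, 0.9, False),
        ],
        seed=1,
    )
    expr, meta, truth = gen_brain_cohort(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted modules, no DEG and no pH effect."""
    cfg = SimCohortConfig(
        n_genes=300, module_specs=[], ph_affected_fraction=0.0, seed=7
    )
    expr, meta, truth = gen_brain_cohort(cfg)
    return expr, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_probe_table():
    """Six probes on one array, all reliable, constant A."""
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(6)],
            "gene_id": ["g1", "g1", "g2", "g2", "g3", "g3"],
            "replicate": "rep1",
            "array": "a1",
            "A": 10.0,
            "M": [0.1, -0.2, 0.3, 0.0, -0.1, 0.2],
            "reliable": True,
        }
    )
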