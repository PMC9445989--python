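import numpy as np
import pandas as pd
import pytest

import icurisk as ir


def cheap_config(n_patients=300, seed=0, **kw):
    """A small cohort with low-rate variables so event generation is fast."""
    variables = [
        ir.VariableSim("creatinine", "timeseries", cadence_hours=24.0, mean=1.1, sd=0.15, between_sd=0.5),
        ir.VariableSim("urine_output", "flow", cadence_hours=6.0, mean=1500, sd=0.25, between_sd=0.45),
        ir.VariableSim("antithrombotics", "medication", cadence_hours=12.0, presence_prob=0.7, n_drugs=4),
        ir.VariableSim("endotracheal_tube", "intervention", cadence_hours=24.0, presence_prob=0.55),
        ir.VariableSim("age", "static", mean=63.3, sd=14.7),
    ]
    truth = [
        ir.TruthTerm(
            ir.FeatureDescriptor("age", "last_value", "patient"),
            cuts=(50.0, 65.0, 78.0), scores=(-0.6, -0.15, 0.25, 0.7),
        ),
        ir.TruthTerm(
            ir.FeatureDescriptor("endotracheal_tube", "days_since_last", "history"),
            cuts=(1.0, 3.0), scores=(0.9, 0.2, -0.25), missing_score=0.3,
        ),
    ]
    kw.setdefault("variables", variables)
    kw.setdefault("truth_terms", truth)
    kw.setdefault("artifact_specs", [])
    return ir.SimConfig(n_patients=n_patients, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A full event-level synthetic cohort shared across tests."""
    cfg = ir.SimConfig(n_patients=500, seed=11)
    transfers, events, truth = ir.generate_cohort(cfg)
    return cfg, transfers, events, truth


@pytest.fixture(scope="session")
def matrix_data():
    """Direct feature-matrix sample with 5 signal + 20 null features."""
    X, y, years, truth = ir.sample_feature_matrix(8000, seed=7)
    return X, y, years, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
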