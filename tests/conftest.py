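import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sleepwave as sw

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_design(groups, study="s", platform="p", zt=None):
    """Minimal valid design table for a list of group labels."""
    ids = [f"{study}.{g}.{i}" for i, g in enumerate(groups)]
    return pd.DataFrame(
        {
            "group": groups,
            "zt_time": zt if zt is not None else [0.0] * len(groups),
            "replicate_group": [f"{study}.{g}" for g in groups],
            "study": study,
            "platform": platform,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def make_dataset(values, groups, feature_ids=None, **kw):
    values = np.asarray(values, float)
    design = make_design(groups, **kw)
    matrix = pd.DataFrame(
        values,
        index=feature_ids or [f"G{i}" for i in range(values.shape[0])],
        columns=design.index,
    )
    return sw.ExpressionDataset(matrix=matrix, design=design)


@pytest.fixture(scope="session")
def sim_default():
    """One study-sized simulation shared across tests (seed fixed)."""
    config = sw.SimulationConfig(n_genes=5000, seed=11)
    return config, *sw.generate(config)


@pytest.fixture(scope="session")
def sim_null():
    """Fully null simulation: no effects, no batch, no circadian term."""
    config = sw.SimulationConfig(
        n_genes=5000, seed=13, k_true=0, batch_strength=0.0,
        frac_up=0.0, frac_down=0.0, frac_late=0.0, frac_circadian=0.0,
        n_positive_controls=0, n_negative_controls=100,
    )
    return config, *sw.generate(config)
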