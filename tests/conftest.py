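import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import oncoscreen as osc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> osc.SimulationConfig:
    """Desk-scale version of the default generator settings."""
    return osc.SimulationConfig(
        n_subtypes=2,
        studies_per_subtype=7,
        genes_per_platform=800,
        samples_per_group=10,
        planted_fraction=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    return osc.generate_collection(small_config)


@pytest.fixture(scope="session")
def small_results(small_collection):
    studies, _ = small_collection
    results = pd.concat(
        [osc.analyze_study(s) for s in studies], ignore_index=True
    )
    return osc.attach_study_metadata(results, studies)


@pytest.fixture()
def toy_study() -> osc.ExpressionStudy:
    """3 genes x 4 samples; GENE_B planted with a strong cancer shift."""
    values = pd.DataFrame(
        {
            "c1": [10.0, 80.0, 5.0],
            "c2": [11.0, 95.0, 5.5],
            "n1": [10.5, 10.0, 5.2],
            "n2": [10.2, 11.0, 5.4],
        },
        index=["GENE_A", "GENE_B", "GENE_C"],
    )
    groups = pd.Series(
        ["cancer", "cancer", "normal", "normal"], index=values.columns
    )
    return osc.ExpressionStudy(
        study_id="toy",
        cancer_type="Brain",
        cancer_subtype="Glioblastoma",
        values=values,
        groups=groups,
    )
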