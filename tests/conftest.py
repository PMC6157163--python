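import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from miregnet import ExpressionMatrix, FeatureRole, PhenotypeVector

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, role=FeatureRole.GENE, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=features, columns=samples), role=role
    )


def make_phenotype(labels, samples=None):
    samples = samples or [f"s{j}" for j in range(len(labels))]
    return PhenotypeVector(sample_ids=list(samples),
                           labels=dict(zip(samples, labels)))


@pytest.fixture
def two_class_phenotype():
    """Six samples, two balanced classes."""
    return make_phenotype(["a", "a", "a", "b", "b", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
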