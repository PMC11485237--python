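import numpy as np
import pandas as pd
import pytest

from fairshift import synthetic_cohort as sc
from fairshift.grid_store import PredictionSet


@pytest.fixture(scope="session")
def canned():
    return sc.canned_scenarios()


@pytest.fixture(scope="session")
def s1_grid(canned):
    return canned["S1"].build()


@pytest.fixture(scope="session")
def s2_grid(canned):
    return canned["S2"].build()


@pytest.fixture(scope="session")
def s3_grid(canned):
    return canned["S3"].build()


def make_prediction_set(scores, labels, groups, attribute="sex",
                        task="disease", polarity="disease_indicator",
                        split="test", environment="src"):
    """Small hand-built PredictionSet for unit tests."""
    n = len(scores)
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "score": np.asarray(scores, dtype=float),
        "label": np.asarray(labels, dtype=int),
        "split": split,
        "environment": environment,
        "task": task,
        attribute: np.asarray(groups, dtype=str),
    })
    return PredictionSet(frame, (attribute,), task, polarity)


@pytest.fixture
def pred_factory():
    return make_prediction_set
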