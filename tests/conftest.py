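import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sustaindeg as sd
from sustaindeg.containers import CountMatrix

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("default")


def make_count_matrix(counts: np.ndarray, stimulus: list[str], timepoint: list[int]) -> CountMatrix:
    """Wrap a raw array into a CountMatrix with a minimal sample table."""
    n, m = counts.shape
    sample_ids = [f"s{j + 1}" for j in range(m)]
    st = pd.DataFrame(
        {
            "stimulus": stimulus,
            "timepoint": timepoint,
            "replicate": list(range(1, m + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(
            counts, index=[f"g{i + 1}" for i in range(n)], columns=sample_ids
        ),
        sample_table=st,
    )


def two_group_matrix(kA: np.ndarray, kB: np.ndarray) -> CountMatrix:
    """Control vs LPS at 12 h from two genes x replicates count blocks."""
    nA, nB = kA.shape[1], kB.shape[1]
    return make_count_matrix(
        np.hstack([kA, kB]),
        ["control"] * nA + ["LPS"] * nB,
        [12] * (nA + nB),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated experiment (shared; treat as read-only)."""
    return sd.simulate_experiment(sd.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_sim):
    cm, _ = default_sim
    return sd.run_pipeline(cm)
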