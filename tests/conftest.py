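import numpy as np
import pandas as pd
import pytest

from plasmir.model import CountMatrix
from plasmir.synth import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture()
def small_rpm_matrix():
    """4 miRNAs x 3 samples with hand-set RPM values."""
    counts = pd.DataFrame(
        [[30, 10, 5], [70, 60, 5], [0, 20, 40], [0, 10, 50]],
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
        columns=["s1", "s2", "s3"],
    )
    rpm = counts / counts.sum(axis=0) * 1e6
    return CountMatrix(counts, rpm)


def make_count_matrix(rng: np.random.Generator, n_mirnas=20, n_samples=5):
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(n_mirnas, n_samples)),
        index=[f"miR-{i:03d}" for i in range(n_mirnas)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CountMatrix(counts)
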