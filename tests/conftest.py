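import numpy as np
import pandas as pd
import pytest

from gutresidency import AnalysisConfig, CountMatrix, SamplingSchedule, PresenceSeries
from gutresidency.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """3 taxa x 4 samples toy count table."""
    return CountMatrix(pd.DataFrame(
        [[5, 0, 2, 1], [0, 0, 0, 0], [100, 50, 25, 10]],
        index=["taxA", "taxB", "taxC"],
        columns=["s1", "s2", "s3", "s4"],
    ))


@pytest.fixture
def small_meta():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "subject_id": ["P1", "P1", "P1", "P1"],
        "date": [0, 7, 14, 28],
    })


def random_presence_series(rng, n_samples=None, taxon="t", subject="s"):
    """A random schedule + random presence pattern (shared oracle input)."""
    n = n_samples or int(rng.integers(2, 40))
    gaps = rng.integers(1, 25, size=n - 1)
    dates = tuple(np.concatenate([[0], np.cumsum(gaps)]).tolist())
    present = tuple(bool(b) for b in rng.random(n) < rng.uniform(0.1, 0.9))
    sched = SamplingSchedule(subject, dates)
    return PresenceSeries(taxon, sched, present)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A scaled-down cohort reused by read-only tests (3 subjects, ~60 taxa)."""
    cfg = SimulationConfig(
        n_subjects=3, span_days_range=(200, 300), n_taxa_range=(50, 70),
        reads_per_sample=5000, seed=11,
    )
    return simulate_cohort(cfg)
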