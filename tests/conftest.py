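import logging

import numpy as np
import pandas as pd
import pytest

import stepsel
from stepsel.pipeline import PipelineConfig, prepare_strata

logging.getLogger("stepsel").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Two cohesive animals, 50 steps each, small landscape with known truth."""
    return stepsel.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_strata(tiny_fixture):
    """Fitting-ready strata (covariates + moderators) for the tiny fixture."""
    fixes, stack, truth = tiny_fixture
    strata, steps, kernel_fits = prepare_strata(fixes, stack, PipelineConfig(seed=11))
    return strata, steps, kernel_fits


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def union_find_partition(pts, threshold):
    """Brute-force O(n^2) union-find over all pairs — the independent grouping oracle."""
    parent = list(range(len(pts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]) <= threshold:
                parent[find(i)] = find(j)
    return [find(i) for i in range(len(pts))]


def partitions_equal(labels_a, labels_b):
    """True when two labelings induce the same partition."""
    seen = {}
    for a, b in zip(labels_a, labels_b):
        if a in seen and seen[a] != b:
            return False
        seen[a] = b
    return len(set(seen.values())) == len(seen)


def make_fix_df(rows):
    """Fix table from (animal, iso_time, x, y, release) tuples."""
    df = pd.DataFrame(rows, columns=["animal_id", "t", "x", "y", "release_date"])
    df["t"] = pd.to_datetime(df["t"])
    df["release_date"] = pd.to_datetime(df["release_date"])
    return df
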