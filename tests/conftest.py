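"""Shared fixtures: a seeded mock-community fit reused across tests.

The MCMC fit is the expensive step, so one reduced-length fit (3 chains x
2,000 iterations) on mocks simulated with nonzero amplification offsets is
computed once per session and shared by calibration and acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

import orcadiet as od
from orcadiet.calibration import SamplerSettings

TRUE_ALPHA_SEED = 11
MOCK_SEED = 12
FIT_SEED = 5

REDUCED = SamplerSettings(chains=3, iterations=2_000, warmup=1_000)


@pytest.fixture(scope="session")
def true_alpha():
    """Per-species offsets drawn Normal(0, 0.3), reference pinned at 0."""
    return od.sim_efficiencies(list(od.MOCK_SPECIES), 0.3, seed=TRUE_ALPHA_SEED)


@pytest.fixture(scope="session")
def mock_fit(true_alpha):
    """(counts, design, estimates): 5 replicates per control at 50k reads."""
    counts, design = od.sim_mock_dataset(
        true_alpha, n_replicates=5, depth=50_000, seed=MOCK_SEED
    )
    estimates = od.fit_efficiencies(counts, design, REDUCED, seed=FIT_SEED)
    return counts, design, estimates


@pytest.fixture(scope="session")
def field_dataset():
    """Small seeded field dataset with replicate pairs."""
    config = od.SimConfig(
        n_field_samples=60,
        n_replicate_pairs=6,
        reads_per_sample=20_000,
        seed=3,
    )
    return od.sim_field_dataset(config)


def identity_accuracy(assigned: pd.Series, truth: pd.Series) -> float:
    """Fraction of samples whose assigned label corresponds one-to-one to
    their true individual (labels mapped to their majority truth; an
    assigned label claimed by two truth individuals scores zero for the
    minority)."""
    truth = truth.loc[assigned.index]
    correct = 0
    claimed: dict[str, str] = {}
    for label, members in truth.groupby(assigned):
        majority = members.value_counts().idxmax()
        if majority not in claimed.values():
            claimed[label] = majority
    for sample in assigned.index:
        if claimed.get(assigned[sample]) == truth[sample]:
            correct += 1
    return correct / len(assigned)
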