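"""Shared fixtures: a small simulated cohort and its polarity coding.

Everything is generated at test time from frozen seeds; the cohort is
session-scoped because several modules exercise the same end-to-end chain.
"""

from __future__ import annotations

import numpy as np
import pytest

import brainpolarity as bp


SMALL_GRID = (12, 12, 6)


@pytest.fixture(scope="session")
def small_config() -> bp.SimulationConfig:
    return bp.SimulationConfig(
        grid_shape=SMALL_GRID,
        n_timepoints=120,
        n_hc=3,
        n_sz=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    subjects, table = bp.generate_cohort(small_config)
    return subjects, table


@pytest.fixture(scope="session")
def coded_cohort(cohort):
    """IAL matrices and polarity proportions for every cohort subject."""
    subjects, table = cohort
    ials, props = [], []
    for s in subjects:
        ial = bp.discretize_ial(bp.zscore_voxels(s.volume))
        p = bp.polarity_proportions(ial)
        bp.polarity_metric(p)
        ials.append(ial)
        props.append(p)
    return ials, props, table


@pytest.fixture(scope="session")
def dpr_model(coded_cohort):
    _, props, _ = coded_cohort
    return bp.fit_dpr([p.stacked() for p in props], k=3, seed=0, replicates=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
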