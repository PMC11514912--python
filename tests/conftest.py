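"""Shared fixtures: one small synthetic blastocyst imaging session.

The session-scoped sequence keeps the expensive rendering + SIFT work
out of individual tests.
"""

import numpy as np
import pytest

from blastomorph import synthgen


@pytest.fixture(scope="session")
def truth():
    """Small ground-truth blastocyst: 60 TE cells, D = 150 um."""
    return synthgen.make_truth(
        n_te_cells=60,
        diameter_um=150.0,
        icm_area_um2=4000.0,
        size_cv_target=0.3,
        seed=11,
        icm_axis=[0.0, 0.0, 1.0],
    )


@pytest.fixture(scope="session")
def sequence(truth):
    """Noiseless 12-view rotational imaging session of `truth`."""
    return synthgen.render_sequence(truth, n_views=12)


@pytest.fixture(scope="session")
def feature_table():
    """Synthetic 226-blastocyst feature table with cohort-style moments."""
    return synthgen.simulate_feature_table(226, seed=42)


@pytest.fixture(scope="session")
def big_feature_table():
    """Large synthetic table for asymptotic statistical checks."""
    return synthgen.simulate_feature_table(10_000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
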