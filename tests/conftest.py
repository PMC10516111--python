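"""Shared fixtures.

The expensive trained-model fixtures are session-scoped and lazily built:
the reference desk-scale run is trained once and shared by every test that
needs a converged model (regularity, atlas recovery, recovery-error
comparisons).
"""

from __future__ import annotations

import numpy as np
import pytest

from cortalign.grid import distortion_weights, make_grid
from cortalign.reference import (held_out_cohort, reference_cohort,
                                 train_reference)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return make_grid(8, 16)


@pytest.fixture
def medium_grid():
    return make_grid(16, 32)


@pytest.fixture
def small_weights(small_grid):
    return distortion_weights(small_grid)


@pytest.fixture(scope="session")
def ref_cohort():
    """The reference synthetic cohort (64x128, n=20, seed 7)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def heldout_cohort():
    """Ten fresh held-out subjects from the same generative conditions."""
    return held_out_cohort()


@pytest.fixture(scope="session")
def reference_run(ref_cohort):
    """Desk-scale model trained for the full reference schedule (expensive)."""
    model, result = train_reference(cohort=ref_cohort)
    return model, result


@pytest.fixture(scope="session")
def tied_run(ref_cohort):
    """Tied-field ablation (v_g = v_f) under otherwise identical conditions
    to the reference run: same cohort, seeds and epoch budget."""
    model, result = train_reference(cohort=ref_cohort, tie_modality_fields=True)
    return model, result
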