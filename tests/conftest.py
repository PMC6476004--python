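"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from serumnmr import CohortConfig, load_reference, preprocess_cohort, simulate_cohort
from serumnmr.chemometrics import fit_oplsda
from serumnmr.reference import COMPARISONS
from serumnmr.significance import COMPARISON_GROUPS, quantify_metabolites


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort(ref):
    """30-sample cohort (10 per group) at default noise levels."""
    cfg = CohortConfig(n_control=10, n_polyp=10, n_crc=10, seed=7)
    return simulate_cohort(ref, cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return preprocess_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_models(small_matrix):
    models = {}
    for comp in COMPARISONS:
        case, base = COMPARISON_GROUPS[comp]
        sub = small_matrix.subset((case, base))
        models[comp] = fit_oplsda(sub, sub.groups, n_orth=1, compute_q2=False)
    return models


@pytest.fixture(scope="session")
def small_quant(small_matrix, ref):
    return quantify_metabolites(small_matrix, ref)


@pytest.fixture(scope="session")
def clean_cohort(ref):
    """Noise-free, jitter-free cohort for exact-recovery checks."""
    cfg = CohortConfig(
        n_control=3, n_polyp=3, n_crc=3, noise_sd=0.0, jitter_sd=0.0,
        baseline_amp=0.0, water_amp=0.0, conc_sigma=0.0, seed=3,
    )
    return simulate_cohort(ref, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
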