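"""Shared fixtures: small variant panels and simulated cohorts.

Everything is generated programmatically; session scope amortizes the larger
simulations across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from bidirmr import (
    CohortProfile,
    StructuralParams,
    harmonize,
    simulate_cohort,
    simulate_study,
    simulate_variants,
)
from bidirmr.simulate import generic_profile


@pytest.fixture(scope="session")
def specs_small():
    """8 BMI + 3 T variants at the study's R² targets."""
    return simulate_variants(8, 3, (0.019, 0.025), seed=11)


@pytest.fixture(scope="session")
def specs_full():
    """The full 97 + 3 panel."""
    return simulate_variants(97, 3, (0.019, 0.025), seed=7)


@pytest.fixture(scope="session")
def small_profiles():
    """Five cohorts scaled to ~1/10 of the study sizes."""
    return tuple(
        CohortProfile(
            p.name, max(p.n // 10, 50), p.bmi_mean, p.bmi_sd, p.t_mean, p.t_sd,
            p.shbg_mean, p.shbg_sd, p.age_mean, p.age_sd, p.smoking_prev,
        )
        for p in StructuralParams().cohort_profiles
    )


@pytest.fixture(scope="session")
def small_params(small_profiles):
    return StructuralParams(cohort_profiles=small_profiles, seed=5)


@pytest.fixture(scope="session")
def small_study(small_params):
    return simulate_study(small_params, n_bmi=12, n_t=3)


@pytest.fixture(scope="session")
def medium_cohort(specs_full):
    """One pooled-scale cohort of 20k men with the default structural model."""
    params = StructuralParams(
        cohort_profiles=(generic_profile(20_000),), heterogeneity_sd=0.0, seed=9
    )
    matrix, table = simulate_cohort(specs_full, 20_000, params, "POOLED", seed=9)
    return harmonize(matrix, specs_full), table, specs_full
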