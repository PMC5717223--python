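"""Shared fixtures: small deterministic cohorts and tables."""

import numpy as np
import pandas as pd
import pytest

from kernsurv import (
    ClinicalTable,
    OmicMatrix,
    SurvivalOutcome,
    ProfileSpec,
    generate_cohort,
)


def make_outcome(time, event, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(len(time))]
    return SurvivalOutcome(pd.DataFrame({"time": time, "event": event}, index=ids))


def make_omic(arr, kind="continuous", name="omic", ids=None, cols=None):
    arr = np.asarray(arr, float)
    ids = ids or [f"S{i:03d}" for i in range(arr.shape[0])]
    cols = cols or [f"g{j:03d}" for j in range(arr.shape[1])]
    return OmicMatrix(pd.DataFrame(arr, index=ids, columns=cols), kind, name)


def standardized_random_omic(n, p, seed, name="omic"):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    return make_omic(Z, name=name)


@pytest.fixture(scope="session")
def small_cohort():
    """n=60 single-profile cohort with real omic signal."""
    return generate_cohort(
        n=60,
        profiles=[ProfileSpec("mRNA", 40, "continuous", 1.0)],
        n_covariates=2,
        beta=[0.5, -0.3],
        censoring_rate=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_profile_cohort():
    """n=50 cohort with one continuous and one binary profile."""
    return generate_cohort(
        n=50,
        profiles=[
            ProfileSpec("mRNA", 30, "continuous", 1.0),
            ProfileSpec("mutation", 60, "binary", 0.5),
        ],
        n_covariates=1,
        beta=[0.4],
        censoring_rate=0.2,
        seed=11,
    )


@pytest.fixture()
def clinical_frame():
    rng = np.random.default_rng(3)
    ids = [f"S{i:03d}" for i in range(30)]
    return ClinicalTable(
        pd.DataFrame(
            {"age": rng.normal(60, 8, 30), "stage": rng.choice(["I", "II", "III"], 30)},
            index=ids,
        )
    )
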