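"""Shared fixtures: one default cohort run reused across the suite."""

import warnings

import numpy as np
import pandas as pd
import pytest

from melomap.config import default_config, noise_free_config
from melomap.pipeline import run_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=123)


@pytest.fixture(scope="session")
def nf_cfg():
    return noise_free_config(seed=123)


@pytest.fixture(scope="session")
def cohort_result(default_cfg):
    """Default cohort run once through the full pipeline."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_cohort(default_cfg, keep_images=True)


@pytest.fixture(scope="session")
def sections(cohort_result):
    return cohort_result.sections


@pytest.fixture(scope="session")
def nf_result(nf_cfg):
    """Noise-free cohort run through the full pipeline."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_cohort(nf_cfg, keep_images=True)


def sections_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Section table taken directly from generator ground truth (no
    imaging): true CNR stands in for the measured mean CNR."""
    df = truth[truth["valid"]].copy()
    df["mean_cnr"] = df["true_cnr"]
    df["n_voxels"] = 1
    return df


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20260924)
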