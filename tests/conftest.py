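"""Shared fixtures: scaled synthetic cohorts and QC outputs."""

import numpy as np
import pandas as pd
import pytest

from methclust.containers import BetaMatrix
from methclust.pipeline import PipelineConfig, run_qc
from methclust.preprocess import select_variant_probes
from methclust.simulate import SimConfig, generate_dataset

TEST_SEED = 7


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast module tests (structure intact)."""
    return SimConfig(
        n_tumors=160,
        n_probes=300,
        n_variant_probes=60,
        qc_fail_counts=(60, 5, 25),
        n_replicated_tumors=24,
        n_failed_samples=4,
        n_ineligible=2,
        seed=TEST_SEED,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_qc(small_dataset):
    cfg = PipelineConfig(seed=TEST_SEED)
    beta = run_qc(
        small_dataset.intensities,
        small_dataset.manifest,
        cfg,
        ineligible_tumors=small_dataset.ineligible_tumors,
    )
    return beta


@pytest.fixture(scope="session")
def small_variant(small_qc):
    return select_variant_probes(small_qc)


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)


def random_beta_matrix(rng, n_probes=20, n_samples=10) -> BetaMatrix:
    vals = rng.beta(2, 2, size=(n_probes, n_samples))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:03d}" for i in range(n_probes)],
            columns=[f"s{j:02d}" for j in range(n_samples)],
        )
    )
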