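"""Shared fixtures: scaled-down synthetic populations and pretrained models.

Everything is generated programmatically at test time from fixed seeds; the
expensive fixtures (population + per-subject pretrained base networks) are
session-scoped and shared between the fusion-training and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fusebci.base_networks import NetworkSpec
from fusebci.synthetic_data import (
    GenParams,
    PopulationSpec,
    SubjectProfile,
    generate_population,
    generate_subject,
)


@pytest.fixture(scope="session")
def compact_gp() -> GenParams:
    return GenParams.compact()


@pytest.fixture(scope="session")
def compact_specs() -> dict:
    return {
        "eeg": NetworkSpec.eeg_compact(),
        "fnirs": NetworkSpec.fnirs_compact(),
    }


@pytest.fixture(scope="session")
def default_subject(compact_gp):
    """One normal-like subject at default signal parameters."""
    return generate_subject(SubjectProfile(), gp=compact_gp, seed=42,
                            subject_id="S42", cohort_tag="normal")


@pytest.fixture(scope="session")
def population6(compact_gp):
    """Six-subject normal population used by the transfer studies."""
    spec = PopulationSpec(n_subjects=6, gen_params=compact_gp, master_seed=5)
    return generate_population(spec)


@pytest.fixture(scope="session")
def pretrained6(population6, compact_specs):
    """Per-subject base models for the six-subject population."""
    from fusebci.fusion_training import pretrain_population

    return pretrain_population(population6, compact_specs, epochs=30, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
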