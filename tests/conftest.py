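"""Shared fixtures: one seeded synthetic family (the study conditions) is
generated once per session and reused by every stage's tests."""

from __future__ import annotations

import pytest

from srnase.annotate import annotate_family
from srnase.identity import build_identity_matrices
from srnase.simulate import FamilyConfig, build_ancestor, generate_family

SESSION_SEED = 1


@pytest.fixture(scope="session")
def family_config() -> FamilyConfig:
    return FamilyConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def family(family_config):
    return generate_family(family_config)


@pytest.fixture(scope="session")
def ancestor(family_config):
    return build_ancestor(family_config)


@pytest.fixture(scope="session")
def annotations(family):
    return annotate_family(family.records + family.homologs)


@pytest.fixture(scope="session")
def matrices(annotations):
    return build_identity_matrices(annotations)


@pytest.fixture(scope="session")
def small_family():
    """A quick, narrow-intron family for tests that need a fresh generation."""
    return generate_family(
        FamilyConfig(
            seed=5,
            n_base_alleles=6,
            n_mutant_derivatives=3,
            intron_length_range=(90, 220),
            n_samples=4,
            trans_specific_fraction=0.34,
        )
    )
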