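"""Shared fixtures: small panels and registry configs."""

from __future__ import annotations

import pytest

from ampliqc.synthetic_registry import (
    ChimeraModel,
    DropoutModel,
    MMTruth,
    PrimerDimerModel,
    RegistryConfig,
    build_allele_panel,
)


@pytest.fixture(scope="session")
def small_panels():
    """Two loci, 6 known + 2 hidden-novel alleles each."""
    return {
        locus: build_allele_panel(locus, n_known=6, n_novel=2, seed=3)
        for locus in ("A", "C")
    }


@pytest.fixture(scope="session")
def single_panel(small_panels):
    return small_panels["A"]


def make_noise_free_config(**overrides) -> RegistryConfig:
    """Config with every artefact channel switched off."""
    defaults = dict(
        n_donors=4,
        seed=11,
        error_rate=0.0,
        off_target_rate=0.0,
        pd_model=PrimerDimerModel(
            baseline={"fluidigm": 0.0, "plate384": 0.0},
            slope={"fluidigm": 0.0, "plate384": 0.0},
        ),
        chimera_model=ChimeraModel(rates={}, default_rate=0.0),
        dropout_model=DropoutModel(
            p_max={"fluidigm": 0.0, "plate384": 0.0}
        ),
        mm_truth=MMTruth(km=10.0, rmax=2000.0),
    )
    defaults.update(overrides)
    return RegistryConfig(**defaults)


@pytest.fixture()
def noise_free_config():
    return make_noise_free_config()
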