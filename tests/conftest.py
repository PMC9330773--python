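"""Shared fixtures: small in-silico libraries and seeded synthetic runs."""

import pytest

from specmatch.lipid_library import LibraryBuildConfig, build_library
from specmatch.synthetic_data import RunConfig, generate_run


@pytest.fixture(scope="session")
def small_lipid_library():
    """A few hundred entries across four classes; fast to build."""
    return build_library(
        LibraryBuildConfig(
            classes=["PC", "PE", "SM", "CE"],
            carbon_range=[14, 16, 18],
            db_range=[0, 1, 2],
        )
    )


@pytest.fixture(scope="session")
def synthetic_run(small_lipid_library):
    """20 planted compounds, 3 samples, fixed seed, no chimerism."""
    return generate_run(
        RunConfig(n_compounds=20, n_samples=3, seed=7), small_lipid_library
    )


@pytest.fixture(scope="session")
def chimeric_run(small_lipid_library):
    """Same study design with heavy chimeric co-isolation."""
    return generate_run(
        RunConfig(n_compounds=20, n_samples=3, chimerism_rate=0.8, seed=11),
        small_lipid_library,
    )
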