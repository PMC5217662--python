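import io

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ffasc.catalog import default_catalog
from ffasc.simulate import generate_catalog, generate_fixture_bundle


@pytest.fixture(scope="session")
def shipped_catalog():
    return default_catalog()


@pytest.fixture()
def small_catalog():
    """12-OG synthetic catalog with multi-member OGs and domain rules."""
    return generate_catalog(
        n_ogs=12,
        category_fractions={"nOG": 4 / 12, "pOG": 5 / 12, "rOG": 3 / 12},
        members_per_og=(1, 3),
        domains_per_member=(0, 3),
        seed=42,
    )


@pytest.fixture()
def decoy_bundle(small_catalog):
    """Fixture bundle with both decoy flavours injected."""
    return generate_fixture_bundle(
        small_catalog,
        n_species=5,
        decoy_params={"evalue": 10, "domain": 10},
        seed=7,
    )


def as_streams(files: dict[str, str]) -> dict[str, io.StringIO]:
    return {k: io.StringIO(v) for k, v in files.items()}
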