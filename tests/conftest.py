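import hypothesis
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")

from chiasmetry.datasets import (
    allium_chiasma_region_counts,
    allium_foci_totals,
    allium_sample_meta,
    chiasma_records_from_region_counts,
    foci_records_from_totals,
)


@pytest.fixture(scope="session")
def allium_records():
    """Chiasma + bivalent records reconstructed from the published marginals."""
    return chiasma_records_from_region_counts()


@pytest.fixture(scope="session")
def allium_foci():
    """Per-cell focus records with the published per-marker totals."""
    return foci_records_from_totals()


@pytest.fixture(scope="session")
def allium_meta():
    return allium_sample_meta()


@pytest.fixture(scope="session")
def region_counts():
    return allium_chiasma_region_counts()


@pytest.fixture(scope="session")
def foci_totals():
    return allium_foci_totals()
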