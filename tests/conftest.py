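import pytest

from medchemfilters.aggregator import load_reference
from medchemfilters.descriptors import compute_descriptors
from medchemfilters.fixtures import aggregator_reference_path, panel_records
from medchemfilters.structural_filters import load_catalog


@pytest.fixture(scope="session")
def panel():
    """The bundled drug-like panel as parsed LibraryRecords."""
    return panel_records()


@pytest.fixture(scope="session")
def panel_descriptors(panel):
    """Descriptor vectors keyed by record id, computed once per session."""
    return {r.record_id: compute_descriptors(r.molecule) for r in panel}


@pytest.fixture(scope="session")
def pains_catalog():
    return load_catalog("pains")


@pytest.fixture(scope="session")
def reos_catalog():
    return load_catalog("reos")


@pytest.fixture(scope="session")
def aggregator_reference():
    return load_reference(aggregator_reference_path())
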