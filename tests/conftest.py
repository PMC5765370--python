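import pytest

from bisallele.synthetic_data import build_paperlike
from bisallele.tables import table1_primers


@pytest.fixture(scope="session")
def paperlike():
    """The ten packaged locus assays over synthetic inserts (fixed seed)."""
    return build_paperlike(seed=1)


@pytest.fixture(scope="session")
def paperlike_by_locus(paperlike):
    return {sim.assay.locus: sim for sim in paperlike}


@pytest.fixture(scope="session")
def table1():
    return table1_primers()
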