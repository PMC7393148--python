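import logging

import pytest

from ghust import FamilySpec, Graph, generate

# the generators are intentionally chatty about largest-component fallbacks;
# keep test output readable
logging.getLogger("ghust").setLevel(logging.ERROR)


@pytest.fixture
def triangle() -> Graph:
    return generate(FamilySpec("complete", {"n": 3}))


@pytest.fixture
def k4() -> Graph:
    return generate(FamilySpec("complete", {"n": 4}))


@pytest.fixture
def p4() -> Graph:
    return generate(FamilySpec("path", {"n": 4}))


@pytest.fixture
def c10() -> Graph:
    return generate(FamilySpec("cycle", {"n": 10}))


@pytest.fixture
def star4() -> Graph:
    """K1,4: hub node '0' with four leaves."""
    return generate(FamilySpec("star", {"n_leaves": 4}))


@pytest.fixture
def bowtie() -> Graph:
    """Two triangles sharing one vertex; nodes (0,1,2) and (2,3,4)."""
    return generate(FamilySpec("bowtie_chain", {"k": 2}))
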