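import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panetsig.genome import CytobandMap, Cytoband, hg19_skeleton
from panetsig.simulate import SimConfig


@pytest.fixture(scope="session")
def genome() -> CytobandMap:
    return hg19_skeleton()


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_map() -> CytobandMap:
    """One metacentric chromosome: two arm bands around an acen pair."""
    return CytobandMap([
        Cytoband("chr1", 0, 40, "p12", "gneg"),
        Cytoband("chr1", 40, 100, "p11", "gpos50"),
        Cytoband("chr1", 100, 120, "p11.1", "acen"),
        Cytoband("chr1", 120, 150, "q11.1", "acen"),
        Cytoband("chr1", 150, 230, "q11", "gneg"),
        Cytoband("chr1", 230, 300, "q12", "gpos50"),
    ])
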