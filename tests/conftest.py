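import numpy as np
import pytest

from lohmap.genome import GenomeModel
from lohmap.simulate import build_marker_map


@pytest.fixture(scope="session")
def genome():
    return GenomeModel()


@pytest.fixture(scope="session")
def markers(genome):
    """Full-scale marker map (~13,000 markers on 16 chromosomes)."""
    return build_marker_map(genome, 13000, seed=1)


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeModel({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def tiny_markers(tiny_genome):
    return build_marker_map(tiny_genome, 1500, seed=2)
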