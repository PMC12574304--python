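import numpy as np
import pytest

from magnetag import simulate as sim
from magnetag.graph import align_fragments


@pytest.fixture(scope="session")
def assembly():
    """One synthetic assembly shared across the suite (seeded)."""
    return sim.gen_assembly(11)


@pytest.fixture(scope="session")
def operon_alignments(assembly):
    """Alignments of every unitig against the reference operon."""
    return align_fragments(assembly.reference, assembly.contig_sequences,
                           min_report_identity=0.5)


@pytest.fixture(scope="session")
def coverage():
    return sim.gen_coverage(22)


@pytest.fixture(scope="session")
def annotations():
    table, lifestyles, truth = sim.gen_annotations(33)
    return table, lifestyles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
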