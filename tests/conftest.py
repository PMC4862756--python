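import pytest

from hybridnet.escore import build_kmer_index
from hybridnet.simulate import ArrayDesign, de_bruijn_sequence, segment_probes


@pytest.fixture(scope="session")
def order10_probes():
    """The full order-10 universal array (38,837 36-nt probes, 9-nt overlap)."""
    return segment_probes(de_bruijn_sequence(10), ArrayDesign())


@pytest.fixture(scope="session")
def order10_index(order10_probes):
    return build_kmer_index(order10_probes, k=8)


@pytest.fixture(scope="session")
def order8_probes():
    """A small universal array (order 8) for cheaper end-to-end tests."""
    return segment_probes(
        de_bruijn_sequence(8), ArrayDesign(order_k=8, probe_length=36, overlap=7)
    )


@pytest.fixture(scope="session")
def order8_index(order8_probes):
    return build_kmer_index(order8_probes, k=8)
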