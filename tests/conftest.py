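import pytest

from virowinnow import simdata
from virowinnow.readfilter import Read


def mk_read(seq: str, rid: str = "r1", lib: str = "SAL_1", qual: int = 40) -> Read:
    return Read(rid, seq, [qual] * len(seq), lib)


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(seed=3, reads_per_library=500)


@pytest.fixture(scope="session")
def small_refs(small_config):
    return simdata.build_references(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_refs):
    reads, manifest = simdata.simulate_reads(small_config, small_refs)
    return reads, manifest
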