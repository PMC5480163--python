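import numpy as np
import pytest

from centsat.readprep import Read

# Fixed 20-bp toy monomer for desk-size alignment tests.
TOY_MONOMER = "ACGTTGCAGTAGCTTACGGA"


def make_read(seq: str, rid: str = "r", q: int = 35, desc: str = "") -> Read:
    return Read(id=rid, seq=seq, qual=tuple([q] * len(seq)), desc=desc)


@pytest.fixture
def rng():
    return np.random.default_rng(20170621)


@pytest.fixture
def toy_monomer():
    return TOY_MONOMER


@pytest.fixture(scope="session")
def small_truth():
    """200-kb genome with one homogeneous (rate-0) CentC array at 50-65.6 kb."""
    from centsat import sim

    spec = sim.GenomeSpec(
        chromosomes=[("chr1", 200_000)],
        arrays=[sim.SatelliteArray("chr1", 50_000, "CentC", 100, 0.0)],
    )
    return sim.build_genome(spec, rng=np.random.default_rng(11))
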