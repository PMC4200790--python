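import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import exomir as ex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ALPHABET = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_config() -> ex.SimulationConfig:
    return ex.SimulationConfig(seed=11, reads_per_library=4000)


@pytest.fixture(scope="session")
def refs(small_config) -> ex.ReferenceSet:
    return ex.build_reference(small_config)


@pytest.fixture(scope="session")
def simulated(refs, small_config):
    """One simulated cell-like library: (reads, truth)."""
    return ex.simulate_reads(refs, small_config, "cells")


@pytest.fixture(scope="session")
def noiseless_config() -> ex.SimulationConfig:
    """No substitutions, no end heterogeneity: every miRNA read is a mature."""
    return ex.SimulationConfig(
        seed=13,
        reads_per_library=5000,
        mismatch_rate=0.0,
        isomir_offset_distribution={0: 1.0},
    )


@pytest.fixture(scope="session")
def noiseless(noiseless_config):
    refs = ex.build_reference(noiseless_config)
    reads, truth = ex.simulate_reads(refs, noiseless_config, "cells")
    return refs, reads, truth


def make_precursor(
    mature5: str,
    *,
    pid: str = "pre-test",
    loop: str = "ACGTACGT",
    pad: str = "AACC",
    chromosome: str = "chr1",
    start: int = 101,
    strand: str = "+",
) -> ex.PrecursorRecord:
    """Perfect-hairpin precursor with the given 5p mature and its 3p mirror."""
    from exomir.util import revcomp

    seq = pad + mature5 + loop + revcomp(mature5) + pad
    m5 = ex.MatureRegion("5p", len(pad), len(pad) + len(mature5))
    a3 = len(pad) + len(mature5) + len(loop)
    m3 = ex.MatureRegion("3p", a3, a3 + len(mature5))
    return ex.PrecursorRecord(
        pid, chromosome, start, start + len(seq) - 1, strand, seq, (m5, m3)
    )
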