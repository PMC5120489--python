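import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnaconcord import Chromosome, GenomeLayout, ProbeMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """Two small chromosomes with off-center centromeres."""
    return GenomeLayout(
        [
            Chromosome("chr1", 100_000, 40_000),
            Chromosome("chr2", 80_000, 36_000),
        ]
    )


@pytest.fixture
def toy_probe_map() -> ProbeMap:
    pos1 = np.arange(1000, 100_000, 1000)  # 99 markers
    pos2 = np.arange(500, 80_000, 800)  # 100 markers
    ids = [f"c1_{i}" for i in range(len(pos1))] + [f"c2_{i}" for i in range(len(pos2))]
    chroms = ["chr1"] * len(pos1) + ["chr2"] * len(pos2)
    return ProbeMap(ids, chroms, np.concatenate([pos1, pos2]))


def make_probe_map_simple(n1: int = 10, n2: int = 0) -> ProbeMap:
    ids = [f"m{i}" for i in range(n1 + n2)]
    chroms = ["chr1"] * n1 + ["chr2"] * n2
    pos = list(range(10, 10 * (n1 + 1), 10)) + list(range(10, 10 * (n2 + 1), 10))
    return ProbeMap(ids, chroms, pos)
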