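import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from asmqc import ReadRecord, make_reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_reference():
    """Two nuclear-like chromosomes plus a low-GC, homopolymer-rich
    mitochondrion-like one."""
    return make_reference(
        [120_000, 80_000, 40_000],
        gc=[0.38, 0.38, 0.17],
        hp_enrichment=[1.0, 1.0, 1.3],
        seed=7,
        names=["chr1", "chr2", "mt"],
    )


def random_reads(rng, n, mean=2000, sd=800, min_len=50):
    """Quick synthetic read set: random lengths, A-filled sequences."""
    lengths = np.maximum(rng.normal(mean, sd, size=n).astype(int), min_len)
    return [ReadRecord(f"r{i}", "A" * int(L)) for i, L in enumerate(lengths)]
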