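import numpy as np
import pytest

from footprint_bench import SimParams, simulate_world
from footprint_bench.intervals import GenomicInterval, IntervalSet


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared by read-only tests."""
    return simulate_world(SimParams(seed=0))


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                        max_len=500, with_scores=False, with_labels=False):
    """Seeded random interval set used by oracle and property tests."""
    ivs = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        score = float(np.round(rng.uniform(0, 100), 3)) if with_scores else None
        label = f"L{rng.integers(0, 5)}" if with_labels else None
        strand = str(rng.choice(["+", "-"])) if with_labels else None
        ivs.append(
            GenomicInterval(chrom, start, start + length, score=score,
                            strand=strand, label=label)
        )
    return IntervalSet(ivs)
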