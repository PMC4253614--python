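import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make perbase importable

from smenrich.genome import GenomeLayout, IntervalSet


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """Single 1 kb chromosome used by the worked examples."""
    return GenomeLayout([("chr1", 1000)])


@pytest.fixture
def two_chrom_layout() -> GenomeLayout:
    return GenomeLayout([("chr1", 1000), ("chr2", 800)])


def random_intervalset(rng: np.random.Generator, layout: GenomeLayout, n: int) -> IntervalSet:
    pairs = []
    for _ in range(n):
        chrom, length = layout.chromosomes[rng.integers(len(layout.chromosomes))]
        s = int(rng.integers(0, length))
        e = int(min(length, s + 1 + rng.integers(0, max(2, length // 10))))
        pairs.append((chrom, s, e))
    return IntervalSet.from_pairs(layout, pairs)


def random_layout(rng: np.random.Generator, max_chroms: int = 3, max_len: int = 40_000) -> GenomeLayout:
    n = int(rng.integers(1, max_chroms + 1))
    return GenomeLayout(
        [(f"chr{i + 1}", int(rng.integers(100, max_len))) for i in range(n)]
    )
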