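from pathlib import Path

import numpy as np
import pytest

from juxtarec.meiosis import RecombinationLandscape, ZygosityMap

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_landscape():
    """100 Mb chromosome at 1 cM/Mb: 100 cM total."""
    return RecombinationLandscape.uniform(100_000_000, 1.0)


@pytest.fixture
def juxtaposed_zygosity():
    """HET measurement interval [45, 55] Mb in an otherwise HOM chromosome."""
    return ZygosityMap.from_het_intervals(100_000_000, [(45_000_000, 55_000_000)])


def random_landscape(rng, chrom_length=10_000_000, max_windows=8, max_rate=5.0):
    n = int(rng.integers(1, max_windows + 1))
    cuts = np.sort(rng.choice(np.arange(1, chrom_length), size=n - 1, replace=False)) if n > 1 else np.array([], dtype=int)
    edges = np.concatenate([[0], cuts, [chrom_length]])
    rates = rng.uniform(0.0, max_rate, size=n)
    return RecombinationLandscape.from_arrays(chrom_length, edges[:-1], edges[1:], rates)


def random_zygosity(rng, chrom_length=10_000_000, max_segments=6):
    n = int(rng.integers(1, max_segments + 1))
    cuts = np.sort(rng.choice(np.arange(1, chrom_length), size=n - 1, replace=False)) if n > 1 else np.array([], dtype=int)
    edges = np.concatenate([[0], cuts, [chrom_length]])
    first = rng.integers(2)
    states = ["HET" if (first + i) % 2 else "HOM" for i in range(n)]
    segs = tuple((int(s), int(e), st) for s, e, st in zip(edges[:-1], edges[1:], states))
    return ZygosityMap(chrom_length, segs)
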