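import numpy as np
import pytest

from crispridesign import BUILTIN_SYSTEMS, Genome, generate_genome


@pytest.fixture
def sth3():
    return BUILTIN_SYSTEMS["Sth3"]


@pytest.fixture
def spa():
    return BUILTIN_SYSTEMS["Spa"]


@pytest.fixture
def polyt_genome():
    """28-bp genome with a single NGGNG site after a T20 protospacer."""
    return Genome(contigs={"c1": "TTTTTTTTTTTTTTTTTTTTAGGCGTTT"})


@pytest.fixture
def random_genomes():
    """Seeded small random genomes spanning the GC range of interest."""

    def make(n: int, min_len: int = 200, max_len: int = 5000, seed: int = 0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            gc = float(rng.choice([0.3, 0.5, 0.67]))
            out.append(generate_genome(length, gc, seed=int(rng.integers(2**31))))
        return out

    return make
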