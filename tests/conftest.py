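import pytest

import urefine as ur


@pytest.fixture
def s3():
    """Three-species caterpillar ((a,b),c)."""
    return ur.parse_newick("((a,b),c);", "species")


@pytest.fixture
def s4():
    """Balanced four-species tree ((a,b),(c,d))."""
    return ur.parse_newick("((a,b),(c,d));", "species")


def bounded_instances(n, offset=0, **kwargs):
    """The oracle-scale random instance family used across the suites."""
    for seed in range(offset, offset + n):
        gene, species, _ = ur.random_bounded_instance(seed, **kwargs)
        yield seed, gene, species
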