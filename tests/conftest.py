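import numpy as np
import pytest

from patrrkit.simulate import LocusConfig, make_locus


@pytest.fixture(scope="session")
def locus_pair():
    """One default synthetic two-species locus shared across tests."""
    return make_locus(LocusConfig(seed=20240917))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [((1 - gc) / 2), gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
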