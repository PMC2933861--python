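import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, n_fraction: float = 0.0) -> str:
    """Random sequence over ACGT with an optional fraction of N positions."""
    letters = rng.choice(list(BASES), size=n)
    if n_fraction > 0:
        mask = rng.random(n) < n_fraction
        letters[mask] = "N"
    return "".join(letters)


@pytest.fixture(scope="session")
def default_genome():
    """The default 15.2 Mb synthetic chromosome and its truth table (seed 11)."""
    from dinuqc.synthetic import default_genome_spec, make_genome

    return make_genome(default_genome_spec(seed=11))
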