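import numpy as np
import pytest

from multiguide import FamilySpec, NucSequence, evolve_family, generate_ancestor

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20230531)


@pytest.fixture
def small_family():
    """Six-species star family with one planted conserved PAM-terminal
    window at [200, 223) and a PAM knockout in sp06."""
    length = 600
    spec = FamilySpec(
        n_species=6,
        length=length,
        divergence=0.1,
        conserved_intervals=((200, 223, True),),
        pam_knockout=frozenset({"sp06"}),
        seed=7,
    )
    ancestor = generate_ancestor(length, seed=7)
    return spec, ancestor, evolve_family(ancestor, spec)
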