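import numpy as np
import pytest

from knotmotif.bpp_engine import boltzmann_weight, enumerate_structures
from knotmotif.structure_core import RnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240116)


def oracle_bpp(seq: RnaSequence, constraints=None) -> np.ndarray:
    """Boltzmann pair frequencies by exhaustive structure enumeration.

    Shared test oracle: independent of the dynamic-programming path, but
    over the same stacking energy model.
    """
    structures = enumerate_structures(seq, constraints)
    n = seq.n
    p = np.zeros((n, n))
    z = 0.0
    for s in structures:
        w = boltzmann_weight(seq, s.as_tuples())
        z += w
        for (i, j) in s.as_tuples():
            p[i, j] += w
            p[j, i] += w
    return p / z


def random_rna(rng, n: int) -> RnaSequence:
    return RnaSequence("".join(rng.choice(list("ACGU"), n)))
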