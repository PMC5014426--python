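import random

import numpy as np
import pytest

from tetrace.genomeio import GenomeAssembly


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def py_random():
    r = random.Random(20240901)
    return r


def random_dna(r: random.Random, n: int) -> str:
    return "".join(r.choice("ACGT") for _ in range(n))


@pytest.fixture
def tiny_genome():
    return GenomeAssembly(
        name="tiny",
        chromosomes={"chr1": "ACGT" * 2500, "chr2": "TTGGCCAA" * 625},
    )
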