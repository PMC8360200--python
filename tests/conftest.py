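import numpy as np
import pytest

from sdrmine.synthetic import (
    ContigSet,
    default_templates,
    generate_contigs,
    plant_genes,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_metagenome():
    """20 contigs with 6 planted family genes and 6 shuffled decoys."""
    contigs = generate_contigs(20, length_mean=1800, length_sd=200, gc=0.5, seed=11)
    contigs, truth = plant_genes(
        contigs,
        default_templates(),
        identities=[35.0, 50.0, 62.0, 75.0, 88.0, 95.0],
        seed=11,
        n_decoys=6,
    )
    return contigs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, n: int, start_met: bool = True) -> str:
    body = "".join(rng.choice(list(AA), size=n))
    return ("M" + body[1:]) if start_met else body


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
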