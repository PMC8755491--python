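import numpy as np
import pytest

from domainer.ortholog_align import CodonAlignment
from domainer.synthetic_data import SimulationConfig, sample_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-gene cohort with a strong intracellular E-R anticorrelation."""
    return sample_cohort(SimulationConfig(n_genes=40, seed=11, target_rho_i=-0.5,
                                          target_rho_e=0.0))


def random_codon_alignment(rng: np.random.Generator, n_codons: int) -> CodonAlignment:
    """Random pair of sense-codon sequences (uniform over the 61 codons)."""
    from domainer._codons import CODON_ARRAY

    ia = rng.integers(0, 61, n_codons)
    ib = rng.integers(0, 61, n_codons)
    return CodonAlignment("a", "b", "".join(CODON_ARRAY[ia]), "".join(CODON_ARRAY[ib]))
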