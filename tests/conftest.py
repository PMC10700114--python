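import numpy as np
import pytest

from relict import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """A 4-contig, 800 kb diploid genome with one hemizygous contig."""
    spec = sd.GenomeSpec(
        n_autosomal_contigs=3,
        n_hemizygous_contigs=1,
        contig_length_bp=200_000,
        seed=1,
    )
    return sd.gen_diploid_genome(spec)


@pytest.fixture(scope="session")
def te_consensus():
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=1000))
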