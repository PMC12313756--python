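import numpy as np
import pytest

from plantglm.synthetic import SyntheticGenomeSpec, generate_genome_with_junctions


@pytest.fixture(scope="session")
def small_genome():
    """A 3-chromosome synthetic genome with planted introns (plus truth)."""
    spec = SyntheticGenomeSpec(
        n_chroms=3, chrom_length_bp=20_000, n_introns=15, seed=11
    )
    return generate_genome_with_junctions(spec)


@pytest.fixture(scope="session")
def stranded_genome():
    """Genome with a mix of plus- and minus-strand planted introns."""
    spec = SyntheticGenomeSpec(
        n_chroms=2, chrom_length_bp=20_000, n_introns=12,
        minus_strand_fraction=0.5, seed=23,
    )
    return generate_genome_with_junctions(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
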