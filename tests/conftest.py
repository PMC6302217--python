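import numpy as np
import pytest

from thermavir.contig import Contig
from thermavir.synth import (GeneratorParams, generate_host_genome,
                             plant_crispr_array)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_contig(rng):
    """10 kb i.i.d. random contig with no planted features."""
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return Contig("random_10k", seq, sample="test", coverage=10.0)


def planted_contig(seed: int, genome_length: int = 10_000, copies: int = 10,
                   mutation_rate: float = 0.01, repeat_length: int = 35,
                   spacer_length: int = 34):
    """A contig carrying exactly one planted CRISPR array, plus its truth."""
    params = GeneratorParams(seed=seed, genome_length=genome_length,
                             array_copies=copies,
                             repeat_mutation_rate=mutation_rate,
                             repeat_length=repeat_length,
                             spacer_length=spacer_length)
    genome, _ = generate_host_genome(params, f"planted_{seed}")
    genome, manifest = plant_crispr_array(genome, params)
    return genome, manifest.planted_arrays[0], params


@pytest.fixture
def planted_array_contig():
    return planted_contig(seed=42)
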