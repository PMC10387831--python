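import numpy as np
import pytest
from hypothesis import settings

from readmimic import NucleotideProfile, ReadRecord
from readmimic.core import generate_biased_reads, random_genome

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    """100 kb single-chromosome uniform-ACGT genome."""
    return random_genome(100_000, np.random.default_rng(11))


@pytest.fixture
def biased_reads(small_genome):
    """2000 reads of length 20, T-enriched (0.9) at positions 18-19."""
    rng = np.random.default_rng(22)
    return generate_biased_reads(
        small_genome, 2000, (20, 20), {18: {"T": 0.9}, 19: {"T": 0.9}}, rng
    )


def single_position_profile(freq_row, n_reads=100):
    """A k=1 profile with one read length 1 and the given (A,C,G,T) row."""
    return NucleotideProfile(
        k=1,
        freqs={1: np.asarray([freq_row], dtype=float)},
        n_reads={1: n_reads},
    )


def reads_from_strings(seqs, quality_char=None):
    return [
        ReadRecord(f"r{i}", s, quality_char * len(s) if quality_char else None)
        for i, s in enumerate(seqs)
    ]
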