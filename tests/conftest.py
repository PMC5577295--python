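import numpy as np
import pytest

from barcodegap import GenusSimulationConfig, simulate_genus, table5_toy
from barcodegap.core_io import AlignedSequenceSet


@pytest.fixture
def toy():
    """Three-column signature toy: six 'CTC', one 'TTC', one 'TTG'."""
    return table5_toy()


@pytest.fixture
def small_genus():
    """Six-species synthetic genus with a forced shared-haplotype pair."""
    return simulate_genus(
        GenusSimulationConfig(
            n_species=6,
            samples_per_species=5,
            seed=11,
            force_sharing_species=(1,),
        )
    )


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int,
                     n_species: int | None = None,
                     alphabet: str = "ACGT") -> AlignedSequenceSet:
    """Uniform-random labelled alignment for property tests."""
    n_species = n_species or max(1, n_seqs // 2)
    chars = np.array(list(alphabet))
    records = []
    for i in range(n_seqs):
        seq = "".join(chars[rng.integers(0, len(chars), size=length)])
        records.append((f"s{i}", f"sp{rng.integers(0, n_species)}", "", seq))
    return AlignedSequenceSet.from_records(records)
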