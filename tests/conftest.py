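import numpy as np
import pytest

from trimsig import Genome, MutationRecord, gen_genome


@pytest.fixture(scope="session")
def random_genome():
    """A two-contig yeast-GC random genome shared across tests."""
    return gen_genome(n_contigs=2, length_per_contig=20_000, gc_fraction=0.38, seed=101)


@pytest.fixture(scope="session")
def big_genome():
    """A 100 kb genome for the simulation-scale checks."""
    return gen_genome(n_contigs=2, length_per_contig=50_000, gc_fraction=0.38, seed=7)


@pytest.fixture()
def tiny_genome():
    return Genome({"c1": "ATGCATGCGT", "c2": "GGCCAATTCG"})


def random_snvs(genome: Genome, n: int, seed: int, sample: str = "S1"):
    """Uniform random SNVs with correct reference bases (helper, not a
    fixture, so tests can vary n/seed)."""
    rng = np.random.default_rng(seed)
    names = list(genome.contigs)
    records = []
    while len(records) < n:
        contig = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(1, genome.length(contig) + 1))
        ref = genome.base(contig, pos)
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        records.append(MutationRecord(sample, contig, pos, ref, alt, vaf=1.0))
    return records
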