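"""Shared fixtures: tiny hand-made genomes and the (expensive) validation run."""

import numpy as np
import pytest

from digs.io import GeneRecord, Genome, GenomeSet
from digs.simulate import BaseGenomeConfig, make_base_genome, simulate_validation


def random_orf(rng: np.random.Generator, n_codons: int = 200) -> str:
    """A random codon-valid ORF (ATG ... stop, no internal stops)."""
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list(bases), 3))
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + str(rng.choice(sorted(stops)))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_genome_pair(rng):
    """Two 10-gene genomes: identical genes except gene 3 carries 6 substitutions."""
    genes_a, genes_b = [], []
    local = np.random.default_rng(7)
    for i in range(10):
        seq = random_orf(local, 200)  # 600 nt
        genes_a.append(GeneRecord(f"a{i}", "A", seq))
        if i == 3:
            pos = local.choice(np.arange(3, 597), size=6, replace=False)
            seq = mutate(seq, pos, local)
        genes_b.append(GeneRecord(f"b{i}", "B", seq))
    return (Genome("A", genes_a), Genome("B", genes_b))


@pytest.fixture(scope="session")
def small_base_genome():
    return make_base_genome(BaseGenomeConfig(n_genes=120, seed=5), "tiny")


@pytest.fixture(scope="session")
def full_validation():
    """Five ~1000-gene base genomes evolved over the full level series,
    compared end to end with and without incompleteness degradation.

    Session-scoped: this is the expensive backbone shared by the LGT-free
    model-agreement and the alpha-recovery checks.
    """
    return simulate_validation(n_base_genomes=5, seed=1, include_incomplete=True)
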