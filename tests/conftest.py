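"""Shared fixtures: small genotype tables, alignments and rasters
generated programmatically."""

import numpy as np
import pytest

from seascape.datatypes import GenotypeTable, SequenceAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_table():
    """Two groups x 3 loci with distinct but overlapping allele pools."""
    rng = np.random.default_rng(7)
    n = 40
    alleles = np.empty((n, 3, 2), dtype=np.int32)
    for j in range(3):
        alleles[: n // 2, j, :] = rng.choice([10, 12, 14], size=(n // 2, 2),
                                             p=[0.6, 0.3, 0.1])
        alleles[n // 2:, j, :] = rng.choice([10, 12, 14], size=(n // 2, 2),
                                            p=[0.1, 0.3, 0.6])
    g = GenotypeTable([f"i{k}" for k in range(n)],
                      ["L1", "L2", "L3"], alleles)
    labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    return g, labels


def random_hwe_table(rng, n, n_loci, n_alleles=6):
    """Panmictic Hardy-Weinberg genotypes with Dirichlet frequencies."""
    alleles = np.empty((n, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        p = rng.dirichlet(np.ones(n_alleles) * 2)
        alleles[:, j, :] = rng.choice(n_alleles, size=(n, 2), p=p) + 1
    return GenotypeTable([f"i{k}" for k in range(n)],
                         [f"L{j}" for j in range(n_loci)], alleles)


@pytest.fixture
def panmictic_table(rng):
    return random_hwe_table(rng, 60, 5)


def mutate_copies(rng, ancestor: str, n: int, n_mut: int) -> SequenceAlignment:
    """n descendants of one ancestor, each with n_mut random changes."""
    seqs = []
    bases = list("ACGT")
    for i in range(n):
        s = list(ancestor)
        for j in rng.choice(len(s), size=n_mut, replace=False):
            s[j] = bases[rng.integers(4)]
        seqs.append("".join(s))
    return SequenceAlignment([f"s{i}" for i in range(n)], seqs)


@pytest.fixture
def small_alignment(rng):
    anc = "".join(np.random.default_rng(3).choice(list("ACGT"), 120))
    return mutate_copies(rng, anc, 12, 6)
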