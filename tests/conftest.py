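import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from orfgenesis.alignio import CdsAlignment
from orfgenesis.phyloevents import PhyloTree
from orfgenesis.synthdata import random_orf


@pytest.fixture
def ref_orf_135() -> str:
    """A 135-codon ORF (408 nt with the stop), the focal gene's dimensions."""
    return random_orf(135, seed=42)


@pytest.fixture
def primate_tree() -> PhyloTree:
    """A small rooted tree with named clades for placement tests."""
    newick = ("((((((human,chimp),gorilla),orangutan),rhesus),"
              "((mouse,rat),rabbit)),(horse,(cat,dog)));")
    return PhyloTree(newick, clades={
        "Hominidae": ["human", "chimp", "gorilla", "orangutan"],
        "Primates": ["human", "chimp", "gorilla", "orangutan", "rhesus"],
        "Glires": ["mouse", "rat", "rabbit"],
        "Laurasiatheria": ["horse", "cat", "dog"],
    })


def pairwise_alignment(ref: str, species_row: str, ref_species="hg19",
                       species="other") -> CdsAlignment:
    """Two-species alignment from pre-gapped rows (ref gaps = insertions)."""
    assert len(ref) == len(species_row)
    colmap = [i for i, c in enumerate(ref) if c != "-"]
    return CdsAlignment(
        ref_species=ref_species,
        ref_cds_length_nt=len(colmap),
        rows={ref_species: ref, species: species_row},
        colmap=colmap,
    )


@pytest.fixture
def make_pair():
    return pairwise_alignment


def random_binary_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random rooted binary tree topology over tips t1..tn."""
    nodes = [f"t{i+1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
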