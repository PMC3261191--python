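import numpy as np
import pytest

from tripletmi.alignments import PairedAlignment
from tripletmi.synthetic import (
    PlantedTriplet,
    SyntheticSpec,
    generate_paired_msa,
    generate_structure_layout,
)


def random_columns(rng, n_cols, n_rows, max_alphabet=4):
    """Random symbol columns over small alphabets, as lists of strings."""
    cols = []
    for _ in range(n_cols):
        k = rng.integers(2, max_alphabet + 1)
        cols.append([str(s) for s in rng.integers(0, k, n_rows)])
    return cols


@pytest.fixture
def tiny_paired():
    """Five species, hand-written columns, with gaps and an ambiguity code."""
    rows = (
        ("sp1", "ACGU", "RDKL"),
        ("sp2", "ACGU", "RDKL"),
        ("sp3", "A-GU", "RDKV"),
        ("sp4", "UCGA", "NEKV"),
        ("sp5", "NCGA", "NEKV"),
    )
    return PairedAlignment(rows=rows, rna_length=4, protein_length=4)


@pytest.fixture(scope="session")
def fig3_bundle():
    """One fig3-planted synthetic bundle with its layout, gap-free."""
    spec = SyntheticSpec(
        n_species=393, rna_length=6, protein_length=10,
        planted_triplets=(PlantedTriplet(1, 1, 2, "fig3", 1.0, "proximal"),),
        gap_rate=0.0, seed=11)
    paired, truth = generate_paired_msa(spec)
    model = generate_structure_layout(spec, truth)
    return spec, paired, truth, model
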