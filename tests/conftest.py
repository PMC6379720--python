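"""Shared fixtures: toy alignments and a random codon-alignment builder."""

from __future__ import annotations

import numpy as np
import pytest

from paircons import CodonAlignment, load_genetic_code
from paircons.codes import CODONS, GAP_CODON


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def code12():
    return load_genetic_code(12)


@pytest.fixture
def toy_alignment():
    """3-species toy: reference [ATG, GCA, CGA]; sp2 differs at column 2."""
    return CodonAlignment(
        group_id="toy",
        reference="ref",
        rows={
            "ref": ("ATG", "GCA", "CGA"),
            "sp1": ("ATG", "GCA", "CGA"),
            "sp2": ("ATG", "GCC", "CGA"),
        },
    )


def make_random_alignment(rng: np.random.Generator, n_species: int = 3,
                          n_codons: int = 30, gap_prob: float = 0.05,
                          mut_prob: float = 0.3,
                          group_id: str = "rand") -> CodonAlignment:
    """Random codon alignment with codon-width gaps and point divergence.

    Built column-first so the ungap-identity invariant holds trivially;
    conservation structure is arbitrary, which is the point: the brute-force
    comparator must agree on anything structurally valid.
    """
    sense = [c for c in CODONS]
    species = ["ref"] + [f"sp{i}" for i in range(1, n_species)]
    columns = []
    for _ in range(n_codons):
        ref_codon = sense[rng.integers(len(sense))]
        col = {}
        for sp in species:
            r = rng.random()
            if sp != "ref" and r < gap_prob:
                col[sp] = GAP_CODON
            elif sp != "ref" and r < gap_prob + mut_prob:
                col[sp] = sense[rng.integers(len(sense))]
            else:
                col[sp] = ref_codon
        columns.append(col)
        # occasionally a column where the reference itself is gapped
        if rng.random() < gap_prob:
            ins = {sp: (sense[rng.integers(len(sense))]
                        if rng.random() < 0.5 else GAP_CODON)
                   for sp in species}
            ins["ref"] = GAP_CODON
            ins[species[1]] = sense[rng.integers(len(sense))]
            columns.append(ins)
    rows = {sp: tuple(col[sp] for col in columns) for sp in species}
    return CodonAlignment(group_id=group_id, reference="ref", rows=rows)
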