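"""Genetic-code tables and codon indexing.

Everything downstream works with DNA codons (``A/C/G/T``); RNA input is
normalized at the I/O layer.  Codons are indexed ``0..63`` in lexicographic
``ACGT`` order, and ordered codon pairs as ``64 * first + second``, which lets
the conservation counters use flat numpy accumulators.

Two translation tables are supported: the standard nuclear code (NCBI table 1,
used for *Saccharomyces*) and the alternative yeast nuclear code (table 12,
used for *Candida albicans*-clade species) in which CTG encodes serine rather
than leucine.  The tables themselves come from Biopython's
:mod:`Bio.Data.CodonTable`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable

from .errors import TranslationError

BASES = "ACGT"
#: All 64 DNA codons in lexicographic order; index i encodes the codon.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
#: Gap token used in codon alignments (codon-width).
GAP_CODON = "---"
STOP = "*"
SUPPORTED_TABLES = (1, 12)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping for one NCBI translation table.

    ``codon_to_aa`` maps each of the 64 DNA codons to a one-letter amino acid,
    with ``"*"`` marking the three stop codons (TAA, TAG, TGA in both
    supported tables).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def amino_acid(self, codon: str) -> str:
        return self.codon_to_aa[codon]


@lru_cache(maxsize=None)
def load_genetic_code(table_id: int) -> GeneticCode:
    """Load translation table 1 (standard) or 12 (alternative yeast nuclear).

    Raises ``ValueError`` for any other id, listing the supported tables.
    """
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(
            f"unsupported translation table {table_id!r}; "
            f"supported tables: {', '.join(map(str, SUPPORTED_TABLES))}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    # Sanity on invariants the rest of the package leans on.
    assert len(mapping) == 64 and sum(v == STOP for v in mapping.values()) == 3
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)


@lru_cache(maxsize=None)
def sense_mask(table_id: int) -> np.ndarray:
    """Boolean mask over the 64 codon indices, True for sense codons."""
    code = load_genetic_code(table_id)
    mask = np.zeros(64, dtype=bool)
    for codon in code.sense_codons:
        mask[CODON_INDEX[codon]] = True
    mask.setflags(write=False)
    return mask


@lru_cache(maxsize=None)
def synonymous_partners(table_id: int) -> dict[str, tuple[str, ...]]:
    """Map each sense codon to the other sense codons encoding the same
    amino acid (empty tuple for single-codon families such as ATG/TGG)."""
    code = load_genetic_code(table_id)
    by_aa: dict[str, list[str]] = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.amino_acid(codon), []).append(codon)
    return {
        codon: tuple(c for c in family if c != codon)
        for family in by_aa.values()
        for codon in family
    }


def translate(sequence: str, code: GeneticCode, strip_stop: bool = True) -> str:
    """Translate a CDS to one-letter amino acids.

    A single trailing stop codon is stripped when ``strip_stop`` is set; an
    internal stop raises :class:`TranslationError` naming the (1-based) codon
    index, as does a length that is not a multiple of 3.
    """
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"sequence length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if strip_stop and codons and codons[-1] in code.codon_to_aa \
            and code.is_stop(codons[-1]):
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons, start=1):
        try:
            aa = code.codon_to_aa[codon]
        except KeyError:
            raise TranslationError(
                f"unrecognized codon {codon!r} at codon {i}", codon_index=i
            ) from None
        if aa == STOP:
            raise TranslationError(
                f"internal stop codon {codon} at codon {i}", codon_index=i)
        out.append(aa)
    return "".join(out)


def strip_trailing_stop(sequence: str, code: GeneticCode) -> str:
    """Remove one trailing stop codon if present (no-op otherwise)."""
    seq = sequence.upper()
    if len(seq) % 3 == 0 and len(seq) >= 3:
        last = seq[-3:]
        if last in code.codon_to_aa and code.is_stop(last):
            return seq[:-3]
    return seq


def pair_label(codon1: str, codon2: str) -> str:
    """Canonical display form of an ordered codon pair, e.g. ``"CGA-CGA"``."""
    return f"{codon1}-{codon2}"


def parse_pair(label: str) -> tuple[str, str]:
    """Inverse of :func:`pair_label`; accepts RNA spellings (U -> T)."""
    parts = label.strip().upper().replace("U", "T").split("-")
    if len(parts) != 2 or any(len(p) != 3 for p in parts):
        raise ValueError(f"not a codon pair label: {label!r}")
    return parts[0], parts[1]


def dipeptide(codon1: str, codon2: str, code: GeneticCode) -> str:
    """Ordered two-letter amino-acid string encoded by a codon pair.

    Stop codons map to ``"*"`` so frame-shifted trinucleotide units (which
    need not be sense codons) can still be grouped.
    """
    return code.codon_to_aa[codon1] + code.codon_to_aa[codon2]
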