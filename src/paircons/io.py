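"""Reading and writing the pipeline's standard formats.

Covers unaligned/aligned FASTA, tab-separated ortholog tables (one row per
orthogroup, one column per species, missing members as a placeholder token),
and plain-text ORF exclusion lists (dubious ORFs / pseudogenes, one id per
line).  Genetic-code loading is re-exported from :mod:`paircons.codes` so this
module is the single entry point for input plumbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .codes import GeneticCode, load_genetic_code  # noqa: F401  (re-export)
from .errors import FastaParseError, OrthologTableError

logger = logging.getLogger(__name__)

DEFAULT_PLACEHOLDER = "---"


def _normalize(seq: str) -> str:
    """Uppercase and convert RNA to DNA spelling; gaps pass through."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Record ids are the first whitespace-delimited token of the header line.
    Sequences are uppercased with U converted to T.  Sequence data appearing
    before any header raises :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    with path.open() as handle:
        # The only structurally malformed case for FASTA is residue data
        # before the first header; locate it for a line-numbered error.
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"sequence data before first FASTA header in {path.name}",
                    line=lineno,
                )
            break
        handle.seek(0)
        return [
            (header.split()[0] if header.split() else "", _normalize(seq))
            for header, seq in SimpleFastaParser(handle)
        ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write ``(id, sequence)`` records wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
            if not seq:
                handle.write("\n")


@dataclass(frozen=True)
class OrthologMember:
    orf_id: str
    sequence: str | None = None


@dataclass
class OrthologGroup:
    """One orthogroup: per-species ORF identifiers and (optionally) their
    unaligned coding sequences."""

    group_id: str
    members: dict[str, OrthologMember]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.members)

    def orf_id(self, species: str) -> str:
        return self.members[species].orf_id

    def sequence(self, species: str) -> str:
        seq = self.members[species].sequence
        if seq is None:
            raise ValueError(
                f"group {self.group_id}: no sequence attached for {species}")
        return seq

    def with_sequences(
        self, seqs_by_species: dict[str, dict[str, str]]
    ) -> "OrthologGroup":
        """Attach sequences looked up per species by ORF id.

        Raises ``KeyError`` naming the missing id if a member cannot be
        resolved in its species' sequence collection.
        """
        members = {}
        for sp, member in self.members.items():
            pool = seqs_by_species[sp]
            if member.orf_id not in pool:
                raise KeyError(
                    f"group {self.group_id}: ORF {member.orf_id!r} not found "
                    f"in sequences for species {sp!r}")
            members[sp] = OrthologMember(member.orf_id, pool[member.orf_id])
        return OrthologGroup(self.group_id, members)


def read_ortholog_table(
    path: str | Path,
    species_order: Sequence[str],
    placeholder: str = DEFAULT_PLACEHOLDER,
    reference: str | None = None,
) -> list[OrthologGroup]:
    """Parse a Pillars-style TSV of orthologs into group skeletons (ids only).

    One row per orthogroup, one column per entry of ``species_order``.  Rows
    with fewer than two non-placeholder entries are dropped.  ``group_id`` is
    the reference species' ORF id when available, else the first member's id.
    A column-count mismatch raises :class:`OrthologTableError` with the row
    number.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    groups: list[OrthologGroup] = []
    n_dropped = 0
    with path.open() as handle:
        for rowno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(species_order):
                raise OrthologTableError(
                    f"expected {len(species_order)} columns for species "
                    f"{list(species_order)}, found {len(fields)}", row=rowno)
            members = {
                sp: OrthologMember(orf.strip())
                for sp, orf in zip(species_order, fields)
                if orf.strip() and orf.strip() != placeholder
            }
            if len(members) < 2:
                n_dropped += 1
                continue
            if reference is not None and reference in members:
                group_id = members[reference].orf_id
            else:
                group_id = next(iter(members.values())).orf_id
            groups.append(OrthologGroup(group_id, members))
    if n_dropped:
        logger.info("dropped %d orthogroup rows with <2 members", n_dropped)
    return groups


@dataclass(frozen=True)
class OrfFilter:
    """Set of ORF identifiers to exclude (dubious ORFs, pseudogenes)."""

    excluded_ids: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_file(cls, path: str | Path) -> "OrfFilter":
        ids = set()
        with Path(path).open() as handle:
            for line in handle:
                line = line.strip()
                if line and not line.startswith("#"):
                    ids.add(line.split()[0])
        return cls(frozenset(ids))


def apply_orf_filter(
    groups: Sequence[OrthologGroup],
    orf_filter: OrfFilter,
    reference: str,
) -> list[OrthologGroup]:
    """Drop groups whose *reference-species* ORF id is excluded.

    Exclusion is keyed on the reference annotation only (exclusion lists are
    per-annotation-database); a non-reference member's id never removes a
    group.  Idempotent, never increases the group count.
    """
    kept = []
    for group in groups:
        if reference in group.members:
            ref_id = group.members[reference].orf_id
        else:
            ref_id = group.group_id
        if ref_id not in orf_filter.excluded_ids:
            kept.append(group)
    removed = len(groups) - len(kept)
    if removed:
        logger.info("ORF filter removed %d of %d groups", removed, len(groups))
    return kept
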