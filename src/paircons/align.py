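"""Codon-aware ortholog alignment: translate, align proteins, back-translate.

Alignments are produced at the amino-acid level (so synonymous divergence
never introduces spurious gaps) and then mapped back onto codons, giving a
:class:`CodonAlignment` whose columns are codon-width tokens.  The aligner is
a self-contained progressive scheme built on global Needleman-Wunsch/Gotoh
with affine gaps and a fixed tie-break (diagonal > up > left) so identical
inputs always yield byte-identical alignments.  Pre-aligned codon FASTA can
be ingested directly as an escape hatch for externally produced alignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .codes import (
    GAP_CODON,
    GeneticCode,
    strip_trailing_stop,
    translate,
)
from .errors import AlignmentError, BacktranslationError, CodonAlignmentError
from .io import OrthologGroup, read_fasta, write_fasta

GAP = "-"
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class CodonAlignment:
    """Per-species rows of codon-width columns (codon or ``---`` gap token).

    Invariants: every row has the same number of columns; removing gap tokens
    from a row reproduces that species' input codon sequence; the designated
    reference species is present.
    """

    group_id: str
    reference: str
    rows: dict[str, tuple[str, ...]]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, species: str) -> tuple[str, ...]:
        """Codon sequence of one species with gap tokens removed."""
        return tuple(c for c in self.rows[species] if c != GAP_CODON)

    def validate(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise CodonAlignmentError(
                f"group {self.group_id}: rows have unequal column counts "
                f"{sorted(lengths)}")
        if self.reference not in self.rows:
            raise CodonAlignmentError(
                f"group {self.group_id}: reference species "
                f"{self.reference!r} missing from alignment")
        if len(self.rows) < 2:
            raise CodonAlignmentError(
                f"group {self.group_id}: alignment needs >=2 species")

    def subset(self, species: Sequence[str],
               reference: str | None = None) -> "CodonAlignment":
        """Restrict to a species subset, dropping columns that become
        gap-only (insertions private to removed species)."""
        reference = reference or self.reference
        rows = {sp: self.rows[sp] for sp in species}
        keep = [
            j for j in range(self.n_columns)
            if any(rows[sp][j] != GAP_CODON for sp in species)
        ]
        return CodonAlignment(
            self.group_id, reference,
            {sp: tuple(rows[sp][j] for j in keep) for sp in species},
        )


def translate_orf(sequence: str, code: GeneticCode) -> str:
    """Translate a CDS (length divisible by 3) to amino acids, stripping one
    trailing stop; internal stops raise naming the codon index."""
    return translate(sequence, code, strip_stop=True)


@lru_cache(maxsize=None)
def _matrix_lookup(name: str) -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(name)
    lookup: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            lookup[(a, b)] = float(mat[a, b])
    return lookup


_M, _X, _Y = 0, 1, 2  # DP states: match/mismatch, gap-in-b (up), gap-in-a (left)
_NEG = -1.0e30


def _gotoh(
    n: int,
    m: int,
    score: Callable[[int, int], float],
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Global affine-gap alignment of abstract positions ``0..n-1`` versus
    ``0..m-1``; end gaps are penalized like internal ones.

    ``score(i, j)`` scores pairing position i of the first object with j of
    the second.  Ties are broken deterministically preferring diagonal, then
    up (gap in second), then left.  Returns the optimal score and the aligned
    path as ``(i, j)`` pairs where ``None`` marks a gap.
    """
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptr[_X, i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptr[_Y, 0, j] = _M if j == 1 else _Y

    def _best(cands: tuple[float, float, float]) -> tuple[float, int]:
        # strict > keeps the earliest (preferred) state on ties: M > X > Y
        best_state = 0
        best_val = cands[0]
        for state in (1, 2):
            if cands[state] > best_val:
                best_val = cands[state]
                best_state = state
        return best_val, best_state

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            val, state = _best((M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            M[i, j] = val + score(i - 1, j - 1)
            ptr[_M, i, j] = state
            val, state = _best((
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            ))
            X[i, j] = val
            ptr[_X, i, j] = state
            val, state = _best((
                M[i, j - 1] + gap_open,
                X[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
            ))
            Y[i, j] = val
            ptr[_Y, i, j] = state

    final, state = _best((M[n, m], X[n, m], Y[n, m]))
    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _X:
            path.append((i - 1, None))
            i -= 1
        else:
            path.append((None, j - 1))
            j -= 1
        state = prev
    path.reverse()
    return final, path


def pairwise_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, str, str]:
    """Global pairwise alignment of two amino-acid strings.

    Returns ``(score, aligned_a, aligned_b)``.
    """
    lookup = _matrix_lookup(matrix)
    score, path = _gotoh(
        len(a), len(b),
        lambda i, j: lookup[(a[i], b[j])],
        gap_open, gap_extend,
    )
    out_a = "".join(GAP if i is None else a[i] for i, _ in path)
    out_b = "".join(GAP if j is None else b[j] for _, j in path)
    return score, out_a, out_b


def _identity(aligned_a: str, aligned_b: str) -> float:
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b)
        if x == y and x != GAP
    )
    denom = min(
        sum(1 for x in aligned_a if x != GAP),
        sum(1 for y in aligned_b if y != GAP),
    )
    return matches / denom if denom else 0.0


def align_proteins(
    seqs: Mapping[str, str],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> dict[str, str]:
    """Progressive multiple alignment of amino-acid sequences.

    Sequences are joined in decreasing order of pairwise identity (the most
    similar pair seeds the alignment; each remaining sequence is added by
    aligning it against the running profile with mean-substitution-score
    column scoring).  Deterministic for fixed inputs and parameters.  Raises
    :class:`AlignmentError` on empty input sequences.
    """
    names = list(seqs)
    for name in names:
        if not seqs[name]:
            raise AlignmentError(f"empty sequence for {name!r}")
    if not names:
        raise AlignmentError("no sequences to align")
    if len(names) == 1:
        return {names[0]: seqs[names[0]]}
    # Fast path: identical sequences align gap-free trivially.  This is the
    # common case for synonymous-only divergence.
    if len({seqs[n] for n in names}) == 1:
        return {n: seqs[n] for n in names}

    lookup = _matrix_lookup(matrix)
    # Guide order from pairwise identities.
    pair_identity: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        _, al_a, al_b = pairwise_align(
            seqs[a], seqs[b], matrix, gap_open, gap_extend)
        pair_identity[(a, b)] = pair_identity[(b, a)] = _identity(al_a, al_b)

    seed = max(
        itertools.combinations(names, 2),
        key=lambda p: (pair_identity[p], -names.index(p[0]), -names.index(p[1])),
    )
    _, al_a, al_b = pairwise_align(
        seqs[seed[0]], seqs[seed[1]], matrix, gap_open, gap_extend)
    msa: dict[str, str] = {seed[0]: al_a, seed[1]: al_b}
    remaining = [n for n in names if n not in msa]

    def profile_score(columns: list[tuple[str, ...]], i: int, res: str) -> float:
        col = columns[i]
        vals = [lookup[(r, res)] for r in col if r != GAP]
        return sum(vals) / len(vals) if vals else 0.0

    while remaining:
        nxt = max(
            remaining,
            key=lambda n: (
                max(pair_identity[(n, m)] for m in msa),
                -names.index(n),
            ),
        )
        remaining.remove(nxt)
        included = list(msa)
        width = len(msa[included[0]])
        columns = [tuple(msa[r][j] for r in included) for j in range(width)]
        seq = seqs[nxt]
        _, path = _gotoh(
            width, len(seq),
            lambda i, j: profile_score(columns, i, seq[j]),
            gap_open, gap_extend,
        )
        new_rows = {name: [] for name in included}
        new_seq_row: list[str] = []
        for i, j in path:
            for name in included:
                new_rows[name].append(GAP if i is None else msa[name][i])
            new_seq_row.append(GAP if j is None else seq[j])
        msa = {name: "".join(new_rows[name]) for name in included}
        msa[nxt] = "".join(new_seq_row)

    # Restore input order and check the gap-removal invariant.
    out = {name: msa[name] for name in names}
    for name in names:
        assert out[name].replace(GAP, "") == seqs[name]
    return out


def backtranslate(
    aa_alignment: Mapping[str, str],
    nt_seqs: Mapping[str, str],
    code: GeneticCode | Mapping[str, GeneticCode],
    group_id: str = "",
    reference: str | None = None,
) -> CodonAlignment:
    """Map an amino-acid alignment back onto codons.

    Per species, the nucleotide CDS (after trailing-stop stripping) must be
    exactly 3x the ungapped aligned length and must translate to the aligned
    amino acids under that species' genetic code; a silent edit therefore
    raises :class:`BacktranslationError` naming the species and column.
    """
    species = list(aa_alignment)
    reference = reference or species[0]
    rows: dict[str, tuple[str, ...]] = {}
    for sp in species:
        sp_code = code[sp] if isinstance(code, Mapping) else code
        aligned = aa_alignment[sp]
        nt = strip_trailing_stop(nt_seqs[sp].upper().replace("U", "T"), sp_code)
        n_aa = sum(1 for c in aligned if c != GAP)
        if len(nt) != 3 * n_aa:
            raise BacktranslationError(
                f"group {group_id}: {sp} nucleotide length {len(nt)} does not "
                f"match {n_aa} aligned residues", species=sp)
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        row: list[str] = []
        k = 0
        for col, aa in enumerate(aligned):
            if aa == GAP:
                row.append(GAP_CODON)
                continue
            codon = codons[k]
            observed = sp_code.codon_to_aa.get(codon)
            if observed != aa and not (observed == "*" and aa == "X"):
                raise BacktranslationError(
                    f"group {group_id}: {sp} codon {codon} at alignment "
                    f"column {col + 1} translates to {observed!r}, aligned "
                    f"amino acid is {aa!r}", species=sp, column=col + 1)
            row.append(codon)
            k += 1
        rows[sp] = tuple(row)
    aln = CodonAlignment(group_id=group_id, reference=reference, rows=rows)
    aln.validate()
    return aln


def align_group(
    group: OrthologGroup,
    code: GeneticCode | Mapping[str, GeneticCode],
    reference: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> CodonAlignment:
    """Translate -> align -> back-translate one orthogroup."""
    proteins = {}
    nts = {}
    for sp in group.species:
        sp_code = code[sp] if isinstance(code, Mapping) else code
        nts[sp] = group.sequence(sp)
        proteins[sp] = translate_orf(nts[sp], sp_code)
    aligned = align_proteins(proteins, matrix, gap_open, gap_extend)
    return backtranslate(aligned, nts, code,
                         group_id=group.group_id, reference=reference)


def read_codon_alignment(path: str | Path, reference: str) -> CodonAlignment:
    """Ingest a pre-aligned FASTA as a codon alignment.

    All records must share one length divisible by 3, and gaps must occur in
    codon-width runs aligned to the reading frame; anything else raises
    :class:`CodonAlignmentError` ("alignment not codon-aware").
    """
    path = Path(path)
    records = read_fasta(path)
    if not records:
        raise CodonAlignmentError(f"{path.name}: empty alignment")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise CodonAlignmentError(
            f"{path.name}: records have unequal lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3 != 0:
        raise CodonAlignmentError(
            f"{path.name}: aligned length {length} not a multiple of 3")
    rows: dict[str, tuple[str, ...]] = {}
    for name, seq in records:
        tokens = []
        for i in range(0, length, 3):
            codon = seq[i:i + 3]
            if GAP in codon and codon != GAP_CODON:
                raise CodonAlignmentError(
                    f"{path.name}: record {name} has a frame-breaking gap at "
                    f"position {i + 1}; alignment not codon-aware")
            tokens.append(codon)
        rows[name] = tuple(tokens)
    aln = CodonAlignment(group_id=path.stem, reference=reference, rows=rows)
    aln.validate()
    return aln


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    write_fasta(
        ((sp, "".join(aln.rows[sp])) for sp in aln.species), path)
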