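"""Position-wise conservation counting for codons and codon pairs.

A reference codon (or adjacent ordered codon pair) is *conserved* when every
species in the alignment carries the identical codon(s) at the identical
alignment location — strict identity, no substitution model.  Counts are
accumulated over a stream of codon alignments into per-codon and per-pair
totals and conserved counts, from which conservation rates are

    rate(codon) = conserved occurrences / total occurrences in the reference
    rate(pair)  = conserved pair occurrences / total pair occurrences

Pair conventions: two consecutive reference codons always contribute to the
pair's total; the pair counts as conserved only if both member columns are
conserved *and* the two columns are consecutive in the alignment (an
insertion column contributed by any species breaks positional identity).
Pairs containing a stop codon are excluded in the coding frame.

The same counting can be run after re-tokenizing the reference nucleotide
sequence at a +1 or +2 offset ("frame-shift control").  Shifted
tri-nucleotide units are not codons, so all 64 unit types are counted there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import CodonAlignment
from .codes import CODON_INDEX, CODONS, GAP_CODON, GeneticCode, sense_mask
from .errors import PairconsError

logger = logging.getLogger(__name__)

_BASE_ORDER = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceView:
    """Reference-anchored view of one codon alignment.

    Arrays are indexed by reference codon position ``k = 0..K-1`` (gap
    columns of the reference row are skipped).
    """

    reference: str
    species: tuple[str, ...]
    cols: np.ndarray           #: alignment column index per reference codon
    codons: np.ndarray         #: reference codon strings, dtype U3
    codon_ids: np.ndarray      #: 0..63 codon indices
    conserved: np.ndarray      #: codon conserved across all species (bool)
    nt_conserved: np.ndarray   #: (K, 3) per-nucleotide conservation (bool)
    species_match: np.ndarray  #: (S, K) row codon identical to reference


def reference_view(aln: CodonAlignment) -> ReferenceView:
    """Build the vectorized reference-anchored view used by all counters."""
    species = aln.species
    arr = np.array([aln.rows[sp] for sp in species], dtype="U3")
    ref_idx = species.index(aln.reference)
    ref = arr[ref_idx]
    cols = np.nonzero(ref != GAP_CODON)[0]
    sub = arr[:, cols]                       # (S, K) codon tokens
    ref_codons = ref[cols]
    species_match = sub == ref_codons[None, :]
    conserved = species_match.all(axis=0)
    # Nucleotide-level: a position is conserved when no species has a gap in
    # that column and all species carry the reference base.
    nongap_all = (sub != GAP_CODON).all(axis=0)
    nt = np.ascontiguousarray(sub).view("U1").reshape(
        len(species), len(cols), 3)
    nt_conserved = (nt == nt[ref_idx][None]).all(axis=0) & nongap_all[:, None]
    try:
        codon_ids = np.array(
            [CODON_INDEX[c] for c in ref_codons], dtype=np.int64)
    except KeyError as exc:
        raise PairconsError(
            f"group {aln.group_id}: non-ACGT codon {exc.args[0]!r} in "
            f"reference row") from None
    return ReferenceView(
        reference=aln.reference,
        species=species,
        cols=cols,
        codons=ref_codons,
        codon_ids=codon_ids,
        conserved=conserved,
        nt_conserved=nt_conserved,
        species_match=species_match,
    )


def is_conserved_column(aln: CodonAlignment, column: int) -> tuple[bool, str]:
    """Whether one alignment column is conserved; returns the reference codon.

    The reference row must be non-gap at ``column`` (callers iterate
    reference-anchored columns only).
    """
    ref_codon = aln.rows[aln.reference][column]
    if ref_codon == GAP_CODON:
        raise PairconsError(
            f"group {aln.group_id}: reference row is a gap at column {column}")
    flag = all(aln.rows[sp][column] == ref_codon for sp in aln.species)
    return flag, ref_codon


@dataclass
class ConservationTable:
    """Accumulated per-codon and per-pair conservation counts.

    ``frame_offset`` 0 holds the coding frame (61 sense codons, 3721 sense
    pairs); offsets 1 and 2 hold shifted tri-nucleotide units (all 64 types).
    Rates are ``NaN`` (missing, never 0) where the total is zero.
    """

    reference: str
    species: tuple[str, ...]
    table_id: int
    frame_offset: int = 0
    codon_total: np.ndarray = field(
        default_factory=lambda: np.zeros(64, dtype=np.int64))
    codon_cons: np.ndarray = field(
        default_factory=lambda: np.zeros(64, dtype=np.int64))
    pair_total: np.ndarray = field(
        default_factory=lambda: np.zeros((64, 64), dtype=np.int64))
    pair_cons: np.ndarray = field(
        default_factory=lambda: np.zeros((64, 64), dtype=np.int64))
    n_alignments: int = 0
    n_pairs_interrupted: int = 0

    @property
    def sense_only(self) -> bool:
        return self.frame_offset == 0

    @property
    def valid_codon_mask(self) -> np.ndarray:
        if self.sense_only:
            return np.asarray(sense_mask(self.table_id))
        return np.ones(64, dtype=bool)

    @property
    def valid_pair_mask(self) -> np.ndarray:
        m = self.valid_codon_mask
        return np.outer(m, m)

    @property
    def total_reference_codons(self) -> int:
        """Total (sense, in frame 0) reference codons counted."""
        return int(self.codon_total.sum())

    @property
    def codon_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = self.codon_cons / self.codon_total
        rates[self.codon_total == 0] = np.nan
        rates[~self.valid_codon_mask] = np.nan
        return rates

    @property
    def pair_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = self.pair_cons / self.pair_total
        rates[self.pair_total == 0] = np.nan
        rates[~self.valid_pair_mask] = np.nan
        return rates

    def codon_dataframe(self) -> pd.DataFrame:
        mask = self.valid_codon_mask
        ids = np.nonzero(mask)[0]
        return pd.DataFrame({
            "codon": [CODONS[i] for i in ids],
            "total": self.codon_total[ids],
            "conserved": self.codon_cons[ids],
            "rate": self.codon_rates[ids],
        })

    def pair_dataframe(self) -> pd.DataFrame:
        mask = self.valid_pair_mask
        i1, i2 = np.nonzero(mask)
        return pd.DataFrame({
            "codon1": [CODONS[i] for i in i1],
            "codon2": [CODONS[i] for i in i2],
            "total": self.pair_total[i1, i2],
            "conserved": self.pair_cons[i1, i2],
            "rate": self.pair_rates[i1, i2],
        })


def _accumulate(
    alignments: Iterable[CodonAlignment],
    table_id: int,
    offset: int,
    count_interrupted_pairs: bool = True,
) -> ConservationTable:
    table: ConservationTable | None = None
    codon_flat = np.zeros(64, dtype=np.int64)
    codon_cons = np.zeros(64, dtype=np.int64)
    pair_flat = np.zeros(64 * 64, dtype=np.int64)
    pair_cons = np.zeros(64 * 64, dtype=np.int64)
    n_interrupted = 0
    n_aln = 0
    species_union: set[str] = set()

    smask = np.asarray(sense_mask(table_id))
    for aln in alignments:
        if table is None:
            table = ConservationTable(
                reference=aln.reference, species=(), table_id=table_id,
                frame_offset=offset)
        elif aln.reference != table.reference:
            raise PairconsError(
                f"mixed reference species: {aln.reference!r} vs "
                f"{table.reference!r}")
        species_union.update(aln.species)
        view = reference_view(aln)
        n_aln += 1
        if offset == 0:
            ids = view.codon_ids
            cons = view.conserved
            sense = smask[ids]
            codon_flat += np.bincount(ids[sense], minlength=64)
            codon_cons += np.bincount(ids[sense & cons], minlength=64)
            if len(ids) >= 2:
                flat = ids[:-1] * 64 + ids[1:]
                psense = sense[:-1] & sense[1:]
                adjacent = np.diff(view.cols) == 1
                pcons = cons[:-1] & cons[1:] & adjacent
                total_mask = psense if count_interrupted_pairs \
                    else psense & adjacent
                pair_flat += np.bincount(flat[total_mask], minlength=64 * 64)
                pair_cons += np.bincount(
                    flat[psense & pcons], minlength=64 * 64)
                n_interrupted += int(np.sum(psense & ~adjacent))
        else:
            ntc = view.nt_conserved.ravel()
            nt_col = np.repeat(view.cols, 3)
            chars = view.codons.view("U1")
            codes = np.searchsorted(_BASE_ORDER, chars)
            n_nt = len(ntc)
            starts = np.arange(offset, n_nt - 2, 3)
            if len(starts) == 0:
                continue
            ucons = (
                ntc[starts] & ntc[starts + 1] & ntc[starts + 2]
                & (nt_col[starts + 1] - nt_col[starts] <= 1)
                & (nt_col[starts + 2] - nt_col[starts + 1] <= 1)
            )
            uid = codes[starts] * 16 + codes[starts + 1] * 4 + codes[starts + 2]
            codon_flat += np.bincount(uid, minlength=64)
            codon_cons += np.bincount(uid[ucons], minlength=64)
            if len(starts) >= 2:
                flat = uid[:-1] * 64 + uid[1:]
                between = nt_col[starts[1:]] - nt_col[starts[:-1] + 2] <= 1
                pcons = ucons[:-1] & ucons[1:] & between
                if count_interrupted_pairs:
                    pair_flat += np.bincount(flat, minlength=64 * 64)
                else:
                    pair_flat += np.bincount(
                        flat[between], minlength=64 * 64)
                pair_cons += np.bincount(flat[pcons], minlength=64 * 64)
                n_interrupted += int(np.sum(~between))

    if table is None:
        raise PairconsError("no alignments supplied")
    table.species = tuple(sorted(species_union))
    table.codon_total = codon_flat
    table.codon_cons = codon_cons
    table.pair_total = pair_flat.reshape(64, 64)
    table.pair_cons = pair_cons.reshape(64, 64)
    table.n_alignments = n_aln
    table.n_pairs_interrupted = n_interrupted
    return table


def accumulate_conservation(
    alignments: Iterable[CodonAlignment],
    code: GeneticCode,
    count_interrupted_pairs: bool = True,
) -> ConservationTable:
    """Count codon and codon-pair conservation in the coding frame.

    ``count_interrupted_pairs`` controls whether a consecutive reference
    codon pair whose columns are separated by an insertion column still
    contributes to the pair's *total* (default: yes; it can never be
    conserved either way).
    """
    return _accumulate(alignments, code.table_id, 0, count_interrupted_pairs)


def shifted_frame_conservation(
    alignments: Iterable[CodonAlignment],
    offset: int,
    code: GeneticCode,
    count_interrupted_pairs: bool = True,
) -> ConservationTable:
    """Count conservation of tri-nucleotide units tokenized at +1 or +2.

    Units are read from the reference row's ungapped nucleotide sequence
    starting at ``offset``; a unit is conserved when all three of its
    nucleotide positions are identical and gap-free across species and its
    alignment columns are consecutive.  All 64 unit types are counted (a
    shifted unit is not a codon, so there is no stop exclusion).
    """
    if offset not in (1, 2):
        raise ValueError("offset must be 1 or 2")
    return _accumulate(alignments, code.table_id, offset,
                       count_interrupted_pairs)


@dataclass(frozen=True)
class OrfConservation:
    """Whole-ORF codon conservation: conserved codons over reference length."""

    orf_id: str
    length_codons: int
    conserved_codons: int

    @property
    def rate(self) -> float:
        return self.conserved_codons / self.length_codons


def orf_conservation_rates(
    alignments: Iterable[CodonAlignment],
) -> list[OrfConservation]:
    """Per-ORF conservation rates (conserved codon count over reference
    codon length).  Zero-length ORFs are excluded with a warning."""
    out = []
    for aln in alignments:
        view = reference_view(aln)
        n = len(view.codon_ids)
        if n == 0:
            logger.warning("group %s: zero-length reference ORF excluded",
                           aln.group_id)
            continue
        out.append(OrfConservation(
            orf_id=aln.group_id,
            length_codons=n,
            conserved_codons=int(view.conserved.sum()),
        ))
    return out


def orf_rate_summary(orfs: Sequence[OrfConservation]) -> dict[str, float]:
    rates = np.array([o.rate for o in orfs])
    return {
        "n_orfs": len(orfs),
        "median_rate": float(np.median(rates)) if len(rates) else float("nan"),
        "mean_rate": float(np.mean(rates)) if len(rates) else float("nan"),
    }


def table_from_dataframes(
    codon_df: pd.DataFrame,
    pair_df: pd.DataFrame,
    reference: str,
    table_id: int,
    frame_offset: int = 0,
    species: Sequence[str] = (),
) -> ConservationTable:
    """Rebuild a :class:`ConservationTable` from exported codon/pair tables
    (the inverse of ``codon_dataframe``/``pair_dataframe``)."""
    table = ConservationTable(
        reference=reference, species=tuple(species), table_id=table_id,
        frame_offset=frame_offset)
    for _, row in codon_df.iterrows():
        i = CODON_INDEX[row["codon"]]
        table.codon_total[i] = int(row["total"])
        table.codon_cons[i] = int(row["conserved"])
    for _, row in pair_df.iterrows():
        i1, i2 = CODON_INDEX[row["codon1"]], CODON_INDEX[row["codon2"]]
        table.pair_total[i1, i2] = int(row["total"])
        table.pair_cons[i1, i2] = int(row["conserved"])
    return table


def local_conservation_profile(
    aln: CodonAlignment, window: int = 10
) -> np.ndarray:
    """Sliding-window mean of the per-codon conserved indicator.

    Windows start at each reference position and are truncated at the ORF
    end; a window at least as long as the ORF collapses to the single
    whole-ORF rate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    view = reference_view(aln)
    ind = view.conserved.astype(float)
    n = len(ind)
    if n == 0:
        raise PairconsError(f"group {aln.group_id}: zero-length ORF")
    if window >= n:
        return np.array([ind.mean()])
    csum = np.concatenate([[0.0], np.cumsum(ind)])
    out = np.empty(n)
    for i in range(n):
        hi = min(i + window, n)
        out[i] = (csum[hi] - csum[i]) / (hi - i)
    return out
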