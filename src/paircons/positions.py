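"""Positional analysis of codon-pair occurrences and enrichment statistics.

Where do conserved occurrences of a focal pair set fall within ORFs?  The
position of an occurrence is the 1-based reference codon index of its first
codon divided by the reference ORF length in codons, so positions lie in
(0, 1].  Random pair sets drawn from the sense-pair universe give the null
distribution of per-set median positions.  Enrichment of a focal set among
outliers uses the one-tailed Fisher exact test (upper hypergeometric tail,
evaluated in log space).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import CodonAlignment
from .codes import sense_mask, CODONS, CODON_INDEX
from .conservation import reference_view
from .errors import PairconsError, SimulationError

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One occurrence of a codon pair in a reference ORF."""

    orf_id: str
    pair: Pair
    start_codon_index: int      #: 1-based position of the pair's first codon
    orf_length_codons: int
    conserved: bool

    @property
    def relative_position(self) -> float:
        return self.start_codon_index / self.orf_length_codons


def collect_occurrences(
    alignments: Iterable[CodonAlignment],
    focal_pairs: Iterable[Pair],
    conserved_only: bool = False,
) -> list[OccurrenceRecord]:
    """Every reference occurrence of each focal pair, with conserved status.

    Conservation follows the pair rules of the conservation counters: both
    codon columns identical across species and consecutive in the alignment.
    """
    focal = list(focal_pairs)
    focal_ids = {(CODON_INDEX[a], CODON_INDEX[b]): (a, b) for a, b in focal}
    out: list[OccurrenceRecord] = []
    for aln in alignments:
        view = reference_view(aln)
        ids = view.codon_ids
        n = len(ids)
        if n < 2:
            continue
        cons = view.conserved
        adjacent = np.diff(view.cols) == 1
        pair_conserved = cons[:-1] & cons[1:] & adjacent
        for (ia, ib), pair in focal_ids.items():
            hits = np.nonzero((ids[:-1] == ia) & (ids[1:] == ib))[0]
            for k in hits:
                is_cons = bool(pair_conserved[k])
                if conserved_only and not is_cons:
                    continue
                out.append(OccurrenceRecord(
                    orf_id=aln.group_id, pair=pair,
                    start_codon_index=int(k) + 1,
                    orf_length_codons=n, conserved=is_cons))
    return out


def occurrence_positions(
    alignments: Iterable[CodonAlignment],
    code_table_id: int,
    conserved_only: bool = True,
) -> dict[Pair, np.ndarray]:
    """Relative positions of every sense pair's occurrences, keyed by pair.

    This is the occurrence universe used to draw random pair sets; with
    ``conserved_only`` only conserved occurrences contribute positions.
    """
    smask = np.asarray(sense_mask(code_table_id))
    by_flat: dict[int, list[float]] = {}
    for aln in alignments:
        view = reference_view(aln)
        ids = view.codon_ids
        n = len(ids)
        if n < 2:
            continue
        cons = view.conserved
        adjacent = np.diff(view.cols) == 1
        keep = smask[ids[:-1]] & smask[ids[1:]]
        if conserved_only:
            keep = keep & cons[:-1] & cons[1:] & adjacent
        pos = np.nonzero(keep)[0]
        flat = ids[pos] * 64 + ids[pos + 1]
        rel = (pos + 1) / n
        for f, r in zip(flat, rel):
            by_flat.setdefault(int(f), []).append(float(r))
    return {
        (CODONS[f // 64], CODONS[f % 64]): np.array(v)
        for f, v in sorted(by_flat.items())
    }


@dataclass(frozen=True)
class SimulationSummary:
    """Median positions of randomly drawn pair sets."""

    n_sets: int
    set_size: int
    seed: int
    medians: tuple[float, ...]

    @property
    def mean_of_medians(self) -> float:
        return float(np.mean(self.medians))

    @property
    def sd_of_medians(self) -> float:
        if len(self.medians) < 2:
            return 0.0
        return float(np.std(self.medians, ddof=1))


def simulate_random_sets(
    occurrence_map: Mapping[Pair, np.ndarray],
    n_sets: int = 100,
    set_size: int = 9,
    seed: int = 0,
    exclude: Iterable[Pair] = (),
) -> SimulationSummary:
    """Median pooled position of ``n_sets`` random ``set_size``-pair sets.

    Pairs are drawn uniformly without replacement from the occurrence
    universe minus ``exclude`` (typically the focal set itself).  A drawn
    set with zero pooled occurrences is redrawn (logged).  Deterministic for
    a fixed seed.
    """
    universe = [p for p in occurrence_map if p not in set(exclude)]
    if len(universe) < set_size:
        raise SimulationError(
            f"universe of {len(universe)} pairs cannot supply sets of "
            f"{set_size}")
    rng = np.random.default_rng(seed)
    medians: list[float] = []
    n_resampled = 0
    while len(medians) < n_sets:
        chosen = rng.choice(len(universe), size=set_size, replace=False)
        pooled = np.concatenate(
            [occurrence_map[universe[i]] for i in chosen])
        if len(pooled) == 0:
            n_resampled += 1
            continue
        medians.append(float(np.median(pooled)))
    if n_resampled:
        logger.info("resampled %d empty random sets", n_resampled)
    return SimulationSummary(n_sets=n_sets, set_size=set_size, seed=seed,
                             medians=tuple(medians))


def fisher_enrichment(
    in_set_hits: int,
    in_set_misses: int,
    out_set_hits: int,
    out_set_misses: int,
    alternative: str = "greater",
) -> float:
    """One-tailed Fisher exact p-value for enrichment of a set among hits.

    Computes the upper hypergeometric tail P(X >= in_set_hits) for a 2x2
    table with fixed margins, by log-space summation of exact log-binomial
    terms.  An all-zero table returns p = 1 with a warning.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' alternative is supported")
    a, b, c, d = in_set_hits, in_set_misses, out_set_hits, out_set_misses
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    total = a + b + c + d
    if total == 0:
        logger.warning("all-zero contingency table; p = 1")
        return 1.0
    set_size = a + b          # size of the focal set
    n_hits = a + c            # number of hits drawn
    lo = max(0, set_size + n_hits - total)
    hi = min(set_size, n_hits)
    if a <= lo:
        return 1.0
    log_denom = _log_comb(total, n_hits)
    log_terms = [
        _log_comb(set_size, k) + _log_comb(total - set_size, n_hits - k)
        - log_denom
        for k in range(a, hi + 1)
    ]
    peak = max(log_terms)
    return float(math.exp(peak) * sum(math.exp(t - peak) for t in log_terms))


def _log_comb(n: int, k: int) -> float:
    return (math.lgamma(n + 1) - math.lgamma(k + 1)
            - math.lgamma(n - k + 1))


@dataclass(frozen=True)
class PositionalSummary:
    median: float
    ecdf_x: np.ndarray       #: sorted positions
    ecdf_y: np.ndarray       #: fraction of occurrences <= x
    first_third_fraction: float


def positional_summary(
    occurrences: Sequence[OccurrenceRecord] | Sequence[float] | np.ndarray,
) -> PositionalSummary:
    """Median, ECDF and first-third fraction of relative positions."""
    if len(occurrences) == 0:
        raise PairconsError("no occurrences to summarize")
    if isinstance(occurrences[0], OccurrenceRecord):
        pos = np.array([o.relative_position for o in occurrences])
    else:
        pos = np.asarray(occurrences, dtype=float)
    order = np.sort(pos)
    frac = np.arange(1, len(order) + 1) / len(order)
    return PositionalSummary(
        median=float(np.median(pos)),
        ecdf_x=order,
        ecdf_y=frac,
        first_third_fraction=float(np.mean(pos <= 1.0 / 3.0)),
    )
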