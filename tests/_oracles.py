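"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most naive style possible —
string manipulation, recursion, exact rational arithmetic — and shares no
code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

GAP3 = "---"


# ---------------------------------------------------------------------------
# Conservation counting: direct nucleotide-column comparison.
# ---------------------------------------------------------------------------

def conservation_counts_bruteforce(rows: dict[str, str], reference: str,
                                   offset: int, stops: set[str]):
    """Count unit / unit-pair totals and conserved counts the slow way.

    ``rows`` maps species to aligned *nucleotide* strings (codon-width gaps
    expected).  Units are trinucleotides tokenized from the reference row's
    ungapped sequence starting at ``offset``; at offset 0 units are codons
    and stop-containing units/pairs are excluded.  A unit is conserved when
    each of its nucleotide columns is gap-free and identical across species
    and the columns sit next to each other in the alignment; a unit pair is
    conserved when both units are and no other column intervenes.

    Returns (unit_total, unit_cons, pair_total, pair_cons) as dicts.
    """
    species = list(rows)
    ref = rows[reference]
    # reference nucleotide positions: (alignment column, base)
    ref_nt = [(i, base) for i, base in enumerate(ref) if base != "-"]
    # per alignment column: conserved iff no gap anywhere and all equal ref
    def nt_conserved(col: int) -> bool:
        base = ref[col]
        for sp in species:
            ch = rows[sp][col]
            if ch == "-" or ch != base:
                return False
        # a species with a codon gap has '-' characters, handled above
        return True

    units = []
    k = offset
    while k + 2 < len(ref_nt):
        cols = [ref_nt[k][0], ref_nt[k + 1][0], ref_nt[k + 2][0]]
        seq = ref_nt[k][1] + ref_nt[k + 1][1] + ref_nt[k + 2][1]
        contiguous = cols[1] - cols[0] == 1 and cols[2] - cols[1] == 1
        cons = contiguous and all(nt_conserved(c) for c in cols)
        units.append({"seq": seq, "cols": cols, "conserved": cons})
        k += 3

    unit_total: dict[str, int] = {}
    unit_cons: dict[str, int] = {}
    pair_total: dict[tuple[str, str], int] = {}
    pair_cons: dict[tuple[str, str], int] = {}
    for u in units:
        if offset == 0 and u["seq"] in stops:
            continue
        unit_total[u["seq"]] = unit_total.get(u["seq"], 0) + 1
        if u["conserved"]:
            unit_cons[u["seq"]] = unit_cons.get(u["seq"], 0) + 1
    for u1, u2 in zip(units, units[1:]):
        if offset == 0 and (u1["seq"] in stops or u2["seq"] in stops):
            continue
        key = (u1["seq"], u2["seq"])
        pair_total[key] = pair_total.get(key, 0) + 1
        adjacent = u2["cols"][0] - u1["cols"][2] == 1
        if u1["conserved"] and u2["conserved"] and adjacent:
            pair_cons[key] = pair_cons.get(key, 0) + 1
    return unit_total, unit_cons, pair_total, pair_cons


def codon_alignment_to_nt_rows(aln) -> dict[str, str]:
    """Flatten a CodonAlignment's codon tokens into nucleotide strings."""
    return {sp: "".join(aln.rows[sp]) for sp in aln.species}


# ---------------------------------------------------------------------------
# Global alignment score by exhaustive enumeration (linear gap penalty).
# ---------------------------------------------------------------------------

def best_alignment_score(a: str, b: str, score, gap: float) -> float:
    """Optimal global alignment score by full recursion over all paths."""
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            options.append(gap + rec(i + 1, j))
        if j < len(b):
            options.append(gap + rec(i, j + 1))
        return max(options)

    return rec(0, 0)


# ---------------------------------------------------------------------------
# Fisher exact: margin-fixed enumeration with exact rationals.
# ---------------------------------------------------------------------------

def fisher_greater_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for the hypergeometric table distribution, exactly."""
    total = a + b + c + d
    set_size = a + b
    hits = a + c
    denom = comb(total, hits)
    num = 0
    for k in range(a, min(set_size, hits) + 1):
        if hits - k > total - set_size:
            continue
        num += comb(set_size, k) * comb(total - set_size, hits - k)
    return Fraction(num, denom) if denom else Fraction(1)


# ---------------------------------------------------------------------------
# Two-sample KS by exhaustive permutation.
# ---------------------------------------------------------------------------

def ks_statistic(xs, ys) -> float:
    pooled = sorted(set(xs) | set(ys))
    d = 0.0
    for t in pooled:
        fx = sum(1 for v in xs if v <= t) / len(xs)
        fy = sum(1 for v in ys if v <= t) / len(ys)
        d = max(d, abs(fx - fy))
    return d


def ks_exact_pvalue(xs, ys) -> Fraction:
    """P(D >= observed) over all label assignments of the pooled sample."""
    observed = ks_statistic(xs, ys)
    pooled = list(xs) + list(ys)
    n = len(xs)
    indices = range(len(pooled))
    hits = 0
    count = 0
    for chosen in itertools.combinations(indices, n):
        count += 1
        sel = set(chosen)
        a = [pooled[i] for i in sel]
        b = [pooled[i] for i in indices if i not in sel]
        if ks_statistic(a, b) >= observed - 1e-12:
            hits += 1
    return Fraction(hits, count)


# ---------------------------------------------------------------------------
# Occurrence scanning.
# ---------------------------------------------------------------------------

def scan_pair_occurrences(ref_codons: list[str], pair: tuple[str, str]):
    """1-based start indices of every occurrence of an ordered codon pair."""
    return [
        k + 1 for k in range(len(ref_codons) - 1)
        if ref_codons[k] == pair[0] and ref_codons[k + 1] == pair[1]
    ]
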