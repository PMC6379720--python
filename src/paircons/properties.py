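"""Gene-property comparisons between ORF sets defined by conserved pairs.

ORFs are partitioned into three sets — those carrying a conserved occurrence
of a focal pair, those carrying a conserved occurrence of a control pair,
and all others — where "conserved" here means the pair occupies the same
alignment columns with identical codons in at least ``min_species`` of the
species present (default 4 of 5, so near-complete conservation qualifies).
Numeric properties (CAI, length, protein abundance, mRNA half-life) are then
compared between sets with two-sample Kolmogorov–Smirnov tests, and the
categorical polysome-association profile with a Pearson chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import CodonAlignment
from .codes import CODON_INDEX
from .conservation import reference_view
from .errors import PairconsError

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

#: Property table columns treated as numeric by default.
NUMERIC_PROPERTIES = ("cai", "length_codons", "protein_abundance",
                      "mrna_half_life")
CATEGORY_PROPERTY = "polysome_category"
POLYSOME_CATEGORIES = ("short_orf", "monosome", "no_enrichment",
                       "polysome", "polysome_top")


@dataclass(frozen=True)
class OrfSetMembership:
    """Partition of analyzed ORFs into focal / control / other sets."""

    focal: frozenset[str]
    control: frozenset[str]
    other: frozenset[str]
    overlap: frozenset[str]    #: ORFs qualifying for both, assigned to focal
    min_species: int

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {"focal": self.focal, "control": self.control,
                "other": self.other}


def _orfs_with_conserved_pair(
    alignments: Sequence[CodonAlignment],
    pairs: Iterable[Pair],
    min_species: int,
) -> frozenset[str]:
    wanted = {(CODON_INDEX[a], CODON_INDEX[b]) for a, b in pairs}
    hits: set[str] = set()
    for aln in alignments:
        view = reference_view(aln)
        ids = view.codon_ids
        if len(ids) < 2:
            continue
        adjacent = np.diff(view.cols) == 1
        # species carrying both codons of the occurrence identically
        both = view.species_match[:, :-1] & view.species_match[:, 1:]
        n_match = both.sum(axis=0)
        for k in np.nonzero(adjacent & (n_match >= min_species))[0]:
            if (int(ids[k]), int(ids[k + 1])) in wanted:
                hits.add(aln.group_id)
                break
    return frozenset(hits)


def define_orf_sets(
    alignments: Sequence[CodonAlignment],
    focal_pairs: Iterable[Pair],
    control_pairs: Iterable[Pair],
    min_species: int = 4,
) -> OrfSetMembership:
    """Partition ORFs by conserved focal / control pair content.

    An ORF joins the focal (control) set iff it contains at least one focal
    (control) pair occurrence identical in sequence and aligned location in
    >= ``min_species`` of the species present.  ORFs qualifying for both are
    assigned to the focal set (the hypothesis under test) and reported in
    ``overlap``.
    """
    focal_hits = _orfs_with_conserved_pair(alignments, focal_pairs, min_species)
    control_hits = _orfs_with_conserved_pair(
        alignments, control_pairs, min_species)
    overlap = focal_hits & control_hits
    if overlap:
        logger.info("%d ORFs qualify for both sets; assigned to focal",
                    len(overlap))
    all_ids = frozenset(a.group_id for a in alignments)
    control = control_hits - focal_hits
    other = all_ids - focal_hits - control
    return OrfSetMembership(
        focal=focal_hits, control=frozenset(control), other=other,
        overlap=frozenset(overlap), min_species=min_species)


def ks_compare(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test.

    Uses the exact small-sample distribution when ``n*m <= 1e4`` and the
    asymptotic formula otherwise.  Empty samples raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise PairconsError("KS test needs nonempty samples")
    method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chisq_categories(
    counts: pd.DataFrame | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-squared on a set-by-category contingency of ORF counts.

    Zero-margin rows/columns are dropped with a warning; a table reduced to
    a single row or column raises.  Returns (statistic, dof, p).
    """
    table = np.asarray(counts, dtype=float)
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d zero rows and %d zero columns",
                       int((~row_ok).sum()), int((~col_ok).sum()))
        table = table[row_ok][:, col_ok]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise PairconsError(
            "chi-squared needs >=2 non-empty rows and columns")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def polysome_contingency(
    properties: pd.DataFrame,
    sets: OrfSetMembership,
    categories: Sequence[str] = POLYSOME_CATEGORIES,
) -> pd.DataFrame:
    """Set-by-category counts of ORFs over polysome categories."""
    props = properties.set_index("orf_id")
    rows = {}
    for name, members in sets.as_dict().items():
        ids = [i for i in members if i in props.index]
        cat = props.loc[ids, CATEGORY_PROPERTY].dropna()
        rows[name] = [int((cat == c).sum()) for c in categories]
    return pd.DataFrame(rows, index=list(categories)).T


def summarize_sets(
    properties: pd.DataFrame,
    sets: OrfSetMembership,
    numeric: Sequence[str] = NUMERIC_PROPERTIES,
) -> pd.DataFrame:
    """Median/mean per property per set plus pairwise KS p-values.

    ``properties`` must carry an ``orf_id`` column; missing values are
    excluded per test with logged counts.  Sets with no overlap against the
    property table are flagged (``n = 0``, no test).
    """
    props = properties.set_index("orf_id")
    set_items = list(sets.as_dict().items())
    records = []
    for prop in numeric:
        if prop not in props.columns:
            logger.warning("property %r missing from table; skipped", prop)
            continue
        samples = {}
        for name, members in set_items:
            ids = [i for i in members if i in props.index]
            vals = props.loc[ids, prop].dropna().to_numpy()
            n_missing = len(members) - len(vals)
            if n_missing:
                logger.debug("%s/%s: %d ORFs without values", prop, name,
                             n_missing)
            samples[name] = vals
        rec: dict[str, object] = {"property": prop}
        for name, vals in samples.items():
            rec[f"{name}_n"] = len(vals)
            rec[f"{name}_median"] = (
                float(np.median(vals)) if len(vals) else np.nan)
            rec[f"{name}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
        for (na, va), (nb, vb) in [
            (set_items[i], set_items[j])
            for i in range(len(set_items)) for j in range(i + 1, len(set_items))
        ]:
            key = f"ks_p_{na}_vs_{nb}"
            if len(samples[na]) and len(samples[nb]):
                _, p = ks_compare(samples[na], samples[nb])
                rec[key] = p
            else:
                rec[key] = np.nan
        records.append(rec)
    return pd.DataFrame(records)
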