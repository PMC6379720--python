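"""Origin-constrained conservation model for codon pairs.

The central statistic: regress each pair's conservation rate ``y`` on the
product ``x`` of its constituent codons' conservation rates, through the
origin (``y = b*x``, least squares, so ``b = sum(xy)/sum(x^2)``).  Pairs whose
conservation exceeds what their codons predict sit above the line; pairs more
than ``k`` residual standard deviations away (default ``k = 3``) are called
outliers.  Around that sit pseudocounted normalized conservation scores,
log-scale z-scores within dipeptide families, within-family rankings,
consistency of outlier calls across independent species comparisons, and the
reading-frame-shift control.

The module follows the statsmodels convention: build a
:class:`CodonPairConservation` model from a conservation table (or directly
from alignments), call :meth:`~CodonPairConservation.fit`, and read
estimates, outlier calls and diagnostic tables off the returned
:class:`CodonPairConservationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import CODONS, GeneticCode, dipeptide, load_genetic_code, pair_label
from .conservation import ConservationTable, accumulate_conservation
from .errors import DegenerateFitError

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _pair_frame(table: ConservationTable) -> tuple[pd.DataFrame, int]:
    """Per-pair design frame (x, y) for pairs with defined rates.

    Returns the frame and the number of valid pairs excluded for undefined
    rates (zero totals).
    """
    valid = table.valid_pair_mask
    defined = valid & (table.pair_total > 0)
    i1, i2 = np.nonzero(defined)
    codon_rates = table.codon_rates
    df = pd.DataFrame({
        "codon1": [CODONS[i] for i in i1],
        "codon2": [CODONS[i] for i in i2],
        "total": table.pair_total[i1, i2],
        "conserved": table.pair_cons[i1, i2],
        "y": table.pair_rates[i1, i2],
        "c1_rate": codon_rates[i1],
        "c2_rate": codon_rates[i2],
    })
    df["x"] = df["c1_rate"] * df["c2_rate"]
    # A pair with occurrences implies both codons have occurrences, but keep
    # the guard for exotic tables.
    bad = df["x"].isna()
    n_excluded = int(valid.sum() - defined.sum() + bad.sum())
    df = df[~bad].reset_index(drop=True)
    return df, n_excluded


@dataclass
class PairFitResult:
    """Origin-constrained fit of pair conservation on codon-rate products.

    ``frame`` has one row per included pair with columns ``codon1, codon2,
    total, conserved, x, y, residual, deviation_sigma`` (signed; positive =
    more conserved than predicted).
    """

    slope: float
    residual_sigma: float
    frame: pd.DataFrame
    n_excluded: int
    weighted: bool = False

    @property
    def rsquared(self) -> float:
        """Uncentered R^2 of the through-origin fit."""
        y = self.frame["y"].to_numpy()
        r = self.frame["residual"].to_numpy()
        denom = float(np.sum(y * y))
        return 1.0 - float(np.sum(r * r)) / denom if denom > 0 else float("nan")

    def pairs(self) -> list[Pair]:
        return list(zip(self.frame["codon1"], self.frame["codon2"]))

    def deviation(self, pair: Pair) -> float:
        sel = (self.frame["codon1"] == pair[0]) & (self.frame["codon2"] == pair[1])
        sub = self.frame.loc[sel, "deviation_sigma"]
        return float(sub.iloc[0]) if len(sub) else float("nan")


def origin_slope(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Closed-form through-origin least squares: ``sum(w x y) / sum(w x^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    sxx = float(np.sum(w * x * x))
    if sxx == 0.0:
        raise DegenerateFitError("all x values are zero")
    return float(np.sum(w * x * y)) / sxx


def fit_origin_line(
    table: ConservationTable, weighted: bool = False
) -> PairFitResult:
    """Least-squares line through the origin: ``slope = sum(xy)/sum(x^2)``.

    Pairs with undefined rates are excluded and counted.  Residual sigma is
    the sample standard deviation (ddof=1) of residuals about the line; with
    ``weighted`` the slope uses per-pair occurrence totals as weights (the
    residual scale stays unweighted).
    """
    frame, n_excluded = _pair_frame(table)
    if len(frame) < 2:
        raise DegenerateFitError(
            f"need >=2 pairs with defined rates, have {len(frame)}")
    x = frame["x"].to_numpy()
    y = frame["y"].to_numpy()
    weights = frame["total"].to_numpy().astype(float) if weighted else None
    slope = origin_slope(x, y, weights)
    residual = y - slope * x
    sigma = float(np.std(residual, ddof=1))
    frame = frame.copy()
    frame["residual"] = residual
    frame["deviation_sigma"] = residual / sigma if sigma > 0 else 0.0
    return PairFitResult(slope=slope, residual_sigma=sigma, frame=frame,
                         n_excluded=n_excluded, weighted=weighted)


def call_outliers(
    fit: PairFitResult, k_sigma: float = 3.0
) -> tuple[frozenset[Pair], frozenset[Pair]]:
    """Pairs deviating more than ``k_sigma`` residual SDs above / below the
    fitted line.  With zero residual sigma (all collinear) both sets are
    empty, with a warning."""
    if fit.residual_sigma == 0:
        logger.warning("residual sigma is 0; no outliers can be called")
        return frozenset(), frozenset()
    dev = fit.frame["deviation_sigma"]
    above = frozenset(
        zip(fit.frame.loc[dev > k_sigma, "codon1"],
            fit.frame.loc[dev > k_sigma, "codon2"]))
    below = frozenset(
        zip(fit.frame.loc[dev < -k_sigma, "codon1"],
            fit.frame.loc[dev < -k_sigma, "codon2"]))
    return above, below


@dataclass
class NormalizedScoreTable:
    """Pseudocounted normalized conservation scores.

    score = (pair_rate + p) / ((codon1_rate + p) * (codon2_rate + p))

    with pseudocount ``p``; ``p = "auto"`` uses the reciprocal of the total
    reference (sense) codon count, the smallest rate increment observable in
    the alignments.
    """

    pseudocount: float
    frame: pd.DataFrame
    n_excluded: int


def normalized_scores(
    table: ConservationTable,
    pseudocount: float | str = "auto",
) -> NormalizedScoreTable:
    """Normalized conservation score per pair with defined rates.

    With ``pseudocount = 0`` any pair whose codon rate is zero gets an
    undefined (NaN) score and is flagged.
    """
    if pseudocount == "auto":
        total = table.total_reference_codons
        if total == 0:
            raise DegenerateFitError("empty table: cannot derive pseudocount")
        p = 1.0 / total
    else:
        p = float(pseudocount)
        if p < 0:
            raise ValueError("pseudocount must be >= 0")
    frame, n_excluded = _pair_frame(table)
    denom = (frame["c1_rate"] + p) * (frame["c2_rate"] + p)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (frame["y"] + p) / denom
    score[denom == 0] = np.nan
    frame = frame.copy()
    frame["score"] = score
    n_undef = int(score.isna().sum())
    if n_undef:
        logger.warning("%d pairs have undefined normalized scores (zero "
                       "codon rates with pseudocount 0)", n_undef)
    return NormalizedScoreTable(pseudocount=p, frame=frame,
                                n_excluded=n_excluded)


def dipeptide_zscores(
    scores: NormalizedScoreTable, code: GeneticCode
) -> pd.DataFrame:
    """z-scores of log normalized scores within dipeptide families.

    Every pair is assigned to the family of pairs encoding the same ordered
    dipeptide under ``code`` (for shifted-frame units, stop-containing units
    group under ``*``).  ``X = ln(score)``; ``z = (X - mu_family) /
    sigma_family`` with sample sigma (ddof=1).  Families of size 1 or with
    zero sigma get ``z = 0`` and ``degenerate = True``.
    """
    frame = scores.frame.copy()
    frame = frame[frame["score"].notna()].reset_index(drop=True)
    frame["dipeptide"] = [
        dipeptide(c1, c2, code)
        for c1, c2 in zip(frame["codon1"], frame["codon2"])
    ]
    frame["log_score"] = np.log(frame["score"].to_numpy())
    grp = frame.groupby("dipeptide")["log_score"]
    frame["mu_dp"] = grp.transform("mean")
    frame["sigma_dp"] = grp.transform(lambda s: s.std(ddof=1))
    sigma = frame["sigma_dp"].to_numpy()
    degenerate = ~(sigma > 0)  # NaN (size-1 family) or exactly 0
    z = np.zeros(len(frame))
    ok = ~degenerate
    z[ok] = (frame["log_score"].to_numpy()[ok] - frame["mu_dp"].to_numpy()[ok]) \
        / sigma[ok]
    frame["z"] = z
    frame["degenerate"] = degenerate
    return frame


def rank_within_dipeptide(
    source: ConservationTable | NormalizedScoreTable,
    code: GeneticCode,
    by: str = "raw_rate",
) -> pd.DataFrame:
    """Rank pairs within their dipeptide family, 1 = most conserved.

    ``by = "raw_rate"`` ranks the pair conservation rate itself; ``by =
    "normalized"`` ranks the normalized score.  Ties share the smallest
    ("min") rank.
    """
    if by == "raw_rate":
        table = source if isinstance(source, ConservationTable) else None
        if table is None:
            frame = source.frame.copy()
        else:
            frame, _ = _pair_frame(table)
        frame["value"] = frame["y"]
    elif by == "normalized":
        if not isinstance(source, NormalizedScoreTable):
            raise ValueError("normalized ranking needs a NormalizedScoreTable")
        frame = source.frame.copy()
        frame["value"] = frame["score"]
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    frame["dipeptide"] = [
        dipeptide(c1, c2, code)
        for c1, c2 in zip(frame["codon1"], frame["codon2"])
    ]
    frame["rank"] = (
        frame.groupby("dipeptide")["value"]
        .rank(method="min", ascending=False)
        .astype(int)
    )
    return frame[["codon1", "codon2", "dipeptide", "value", "rank"]]


def cross_comparison_consistency(
    fits: Mapping[str, PairFitResult],
    thresholds: Sequence[float] = (2.0, 3.0),
) -> pd.DataFrame:
    """Per-pair deviations across several independent comparisons.

    A pair's flag at threshold ``k`` is true iff its deviation exceeds ``k``
    in *every* comparison where the pair has defined rates; pairs missing
    from at least one comparison carry ``incomplete = True``.
    """
    if not fits:
        raise ValueError("need at least one comparison")
    columns = {}
    for name, fit in fits.items():
        idx = [pair_label(c1, c2)
               for c1, c2 in zip(fit.frame["codon1"], fit.frame["codon2"])]
        columns[name] = pd.Series(
            fit.frame["deviation_sigma"].to_numpy(), index=idx)
    out = pd.DataFrame(columns)
    out.index.name = "pair"
    defined = out.notna()
    out["incomplete"] = ~defined.all(axis=1)
    for k in thresholds:
        above = (out[list(fits)] > k) | ~defined
        out[f"above_{k:g}_sigma_all"] = above.all(axis=1) & defined.any(axis=1)
    return out


def frame_shift_control(
    tables: Mapping[int, ConservationTable],
    focal_pairs: Iterable[Pair],
    code: GeneticCode,
    pseudocount: float | str = "auto",
) -> pd.DataFrame:
    """Relative conservation of focal six-nucleotide sequences per frame.

    For frame 0 this is the ordinary dipeptide z-score of the codon pair.
    For frames +1/+2 the same hexamer is scored as a pair of shifted
    tri-nucleotide units, with z computed within the family of unit pairs
    sharing the same translated unit-pair string (stops grouped under
    ``*``).  A hexamer never occurring as a unit pair in a frame is flagged
    ``absent``.
    """
    focal = list(focal_pairs)
    rows = []
    for frame_offset in sorted(tables):
        table = tables[frame_offset]
        z_frame = dipeptide_zscores(normalized_scores(table, pseudocount), code)
        z_frame = z_frame.set_index(
            z_frame["codon1"] + "-" + z_frame["codon2"])
        for c1, c2 in focal:
            label = pair_label(c1, c2)
            if label in z_frame.index:
                rec = z_frame.loc[label]
                rows.append({
                    "frame": frame_offset, "codon1": c1, "codon2": c2,
                    "family": rec["dipeptide"], "score": rec["score"],
                    "log_score": rec["log_score"], "z": rec["z"],
                    "absent": False,
                })
            else:
                rows.append({
                    "frame": frame_offset, "codon1": c1, "codon2": c2,
                    "family": dipeptide(c1, c2, code), "score": np.nan,
                    "log_score": np.nan, "z": np.nan, "absent": True,
                })
    return pd.DataFrame(rows)


class CodonPairConservation:
    """Model: codon-pair conservation against constituent-codon conservation.

    Parameters
    ----------
    table:
        Accumulated coding-frame :class:`ConservationTable`.
    code:
        Genetic code; defaults to the table's translation table.
    pseudocount:
        Pseudocount for normalized scores; ``"auto"`` (default) uses the
        reciprocal of the total reference codon count.
    weighted:
        Weight the origin fit by per-pair occurrence totals (default off).

    Examples
    --------
    >>> model = CodonPairConservation.from_alignments(alignments, code)
    >>> res = model.fit()
    >>> res.slope, res.outliers_above              # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(
        self,
        table: ConservationTable,
        code: GeneticCode | None = None,
        pseudocount: float | str = "auto",
        weighted: bool = False,
    ):
        self.table = table
        self.code = code or load_genetic_code(table.table_id)
        self.pseudocount = pseudocount
        self.weighted = weighted

    @classmethod
    def from_alignments(
        cls,
        alignments: Iterable,
        code: GeneticCode,
        pseudocount: float | str = "auto",
        weighted: bool = False,
    ) -> "CodonPairConservation":
        table = accumulate_conservation(alignments, code)
        return cls(table, code=code, pseudocount=pseudocount,
                   weighted=weighted)

    def fit(self, k_sigma: float = 3.0,
            outlier_route: str = "residuals") -> "CodonPairConservationResults":
        """Fit the origin-constrained line and call outliers at ``k_sigma``.

        ``outlier_route`` selects what deviates: ``"residuals"`` (default)
        uses residuals of pair rates about the fitted line; ``"normalized"``
        uses the pseudocounted normalized scores' own distribution.
        """
        if outlier_route not in ("residuals", "normalized"):
            raise ValueError(f"unknown outlier route {outlier_route!r}")
        fit = fit_origin_line(self.table, weighted=self.weighted)
        return CodonPairConservationResults(self, fit, k_sigma, outlier_route)


class CodonPairConservationResults:
    """Results of :meth:`CodonPairConservation.fit`."""

    def __init__(self, model: CodonPairConservation, fit: PairFitResult,
                 k_sigma: float, outlier_route: str):
        self.model = model
        self.fit_result = fit
        self.k_sigma = k_sigma
        self.outlier_route = outlier_route

    # -- estimates -------------------------------------------------------
    @property
    def slope(self) -> float:
        return self.fit_result.slope

    @property
    def residual_sigma(self) -> float:
        return self.fit_result.residual_sigma

    @property
    def rsquared(self) -> float:
        return self.fit_result.rsquared

    @property
    def params(self) -> pd.Series:
        return pd.Series({"slope": self.slope})

    @property
    def deviations(self) -> pd.Series:
        frame = self.fit_result.frame
        idx = [pair_label(a, b)
               for a, b in zip(frame["codon1"], frame["codon2"])]
        return pd.Series(frame["deviation_sigma"].to_numpy(), index=idx,
                         name="deviation_sigma")

    # -- outliers --------------------------------------------------------
    @cached_property
    def _outliers(self) -> tuple[frozenset[Pair], frozenset[Pair]]:
        if self.outlier_route == "residuals":
            return call_outliers(self.fit_result, self.k_sigma)
        frame = self.normalized.frame
        score = frame["score"].to_numpy()
        mu, sd = np.nanmean(score), np.nanstd(score, ddof=1)
        if not sd > 0:
            logger.warning("normalized-score sigma is 0; no outliers")
            return frozenset(), frozenset()
        z = (score - mu) / sd
        pairs = list(zip(frame["codon1"], frame["codon2"]))
        above = frozenset(p for p, v in zip(pairs, z) if v > self.k_sigma)
        below = frozenset(p for p, v in zip(pairs, z) if v < -self.k_sigma)
        return above, below

    @property
    def outliers_above(self) -> frozenset[Pair]:
        return self._outliers[0]

    @property
    def outliers_below(self) -> frozenset[Pair]:
        return self._outliers[1]

    # -- derived tables --------------------------------------------------
    @cached_property
    def normalized(self) -> NormalizedScoreTable:
        return normalized_scores(self.model.table, self.model.pseudocount)

    @cached_property
    def dipeptide_z(self) -> pd.DataFrame:
        return dipeptide_zscores(self.normalized, self.model.code)

    def rank_within_dipeptide(self, by: str = "raw_rate") -> pd.DataFrame:
        source = self.model.table if by == "raw_rate" else self.normalized
        return rank_within_dipeptide(source, self.model.code, by=by)

    def pair_table(self) -> pd.DataFrame:
        """Fit frame plus outlier flags, suitable for TSV export."""
        frame = self.fit_result.frame.copy()
        above, below = self._outliers
        pairs = list(zip(frame["codon1"], frame["codon2"]))
        frame["outlier"] = [
            "above" if p in above else "below" if p in below else ""
            for p in pairs
        ]
        return frame

    def summary(self) -> str:
        fit = self.fit_result
        above, below = self._outliers
        lines = [
            "Codon pair conservation: origin-constrained fit",
            "=" * 48,
            f"reference species        {self.model.table.reference}",
            f"species compared         {len(self.model.table.species)}",
            f"alignments               {self.model.table.n_alignments}",
            f"pairs included           {len(fit.frame)}",
            f"pairs excluded (no data) {fit.n_excluded}",
            f"slope                    {fit.slope:.4f}",
            f"residual sigma           {fit.residual_sigma:.5f}",
            f"uncentered R^2           {fit.rsquared:.4f}",
            f"outliers >{self.k_sigma:g} sigma above  {len(above)}",
            f"outliers >{self.k_sigma:g} sigma below  {len(below)}",
        ]
        if above:
            top = sorted(
                above,
                key=lambda p: -fit.deviation(p))[:10]
            lines.append("top above-line pairs     " + ", ".join(
                f"{pair_label(*p)} ({fit.deviation(p):.1f}s)" for p in top))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CodonPairConservationResults slope={self.slope:.3f} "
                f"sigma={self.residual_sigma:.4f} "
                f"n={len(self.fit_result.frame)}>")
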