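"""Origin-constrained fit, normalized scores, dipeptide z-scores, rankings."""

import numpy as np
import pandas as pd
import pytest

from paircons import (
    ConservationTable,
    call_outliers,
    cross_comparison_consistency,
    dipeptide_zscores,
    fit_origin_line,
    frame_shift_control,
    normalized_scores,
    rank_within_dipeptide,
    CodonPairConservation,
)
from paircons.codes import CODON_INDEX, load_genetic_code
from paircons.errors import DegenerateFitError
from paircons.model import NormalizedScoreTable, PairFitResult, origin_slope
from paircons.simulate import SyntheticSpec, generate, to_alignments


def crafted_table(codon_counts, pair_counts, table_id=1):
    """Build a ConservationTable directly from {codon: (total, cons)} and
    {(c1, c2): (total, cons)}."""
    t = ConservationTable(reference="ref", species=("ref", "sp1"),
                          table_id=table_id)
    for codon, (total, cons) in codon_counts.items():
        t.codon_total[CODON_INDEX[codon]] = total
        t.codon_cons[CODON_INDEX[codon]] = cons
    for (c1, c2), (total, cons) in pair_counts.items():
        t.pair_total[CODON_INDEX[c1], CODON_INDEX[c2]] = total
        t.pair_cons[CODON_INDEX[c1], CODON_INDEX[c2]] = cons
    return t


class TestOriginSlope:
    def test_two_point_closed_form(self):
        # {(1,1),(2,1)}: slope = (1*1 + 2*1) / (1 + 4) = 0.6
        slope = origin_slope([1.0, 2.0], [1.0, 1.0])
        assert slope == pytest.approx(0.6)
        residuals = np.array([1.0, 1.0]) - slope * np.array([1.0, 2.0])
        assert residuals == pytest.approx([0.4, -0.2])

    def test_matches_closed_form_to_machine_precision(self):
        rng = np.random.default_rng(1)
        x = rng.random(500)
        y = 1.2 * x + rng.normal(0, 0.05, 500)
        assert origin_slope(x, y) == pytest.approx(
            np.sum(x * y) / np.sum(x * x), abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateFitError):
            origin_slope([0.0, 0.0], [1.0, 2.0])


class TestFitOriginLine:
    def test_collinear_gives_zero_sigma_and_no_outliers(self):
        # y = x exactly for every pair
        table = crafted_table(
            {"GCA": (10, 5), "CGT": (10, 8), "AAA": (10, 2)},
            {("GCA", "CGT"): (10, 4),    # y = 0.4  = 0.5*0.8
             ("CGT", "AAA"): (100, 16),  # y = 0.16 = 0.8*0.2
             ("AAA", "GCA"): (100, 10)}, # y = 0.1  = 0.2*0.5
        )
        fit = fit_origin_line(table)
        assert fit.slope == pytest.approx(1.0)
        assert fit.residual_sigma == pytest.approx(0.0, abs=1e-15)
        above, below = call_outliers(fit, 3.0)
        assert above == frozenset() and below == frozenset()

    def test_deviation_consistency(self):
        table = crafted_table(
            {"GCA": (100, 50), "CGT": (100, 80), "AAA": (100, 20)},
            {("GCA", "CGT"): (50, 30), ("CGT", "AAA"): (50, 5),
             ("AAA", "GCA"): (50, 6), ("GCA", "AAA"): (50, 4)},
        )
        fit = fit_origin_line(table)
        frame = fit.frame
        # |deviation_sigma| must equal |residual| / sigma to 1e-12
        np.testing.assert_allclose(
            frame["deviation_sigma"],
            frame["residual"] / fit.residual_sigma, atol=1e-12)
        # slope equals the closed form over the included pairs
        assert fit.slope == pytest.approx(
            origin_slope(frame["x"], frame["y"]), abs=1e-14)

    def test_undefined_pairs_excluded_and_counted(self):
        table = crafted_table(
            {"GCA": (100, 50), "CGT": (100, 80)},
            {("GCA", "CGT"): (50, 30), ("CGT", "GCA"): (50, 20)},
        )
        fit = fit_origin_line(table)
        assert len(fit.frame) == 2
        assert fit.n_excluded == 3721 - 2

    def test_outlier_sets_disjoint_on_genome(self, code1):
        dataset = generate(SyntheticSpec(n_genes=60, seed=2,
                                         gene_length_range=(80, 200)))
        res = CodonPairConservation.from_alignments(
            to_alignments(dataset), code1).fit()
        assert not (res.outliers_above & res.outliers_below)


class TestNormalizedScores:
    def test_independence_case(self):
        table = crafted_table(
            {"GCA": (100, 50), "CGT": (100, 50)},
            {("GCA", "CGT"): (100, 25), ("CGT", "GCA"): (100, 25)},
        )
        scores = normalized_scores(table, pseudocount=0.0)
        assert scores.frame["score"].tolist() == pytest.approx([1.0, 1.0])

    def test_pseudocount_arithmetic(self):
        table = crafted_table(
            {"GCA": (100, 50), "CGT": (100, 50)},
            {("GCA", "CGT"): (100, 25), ("CGT", "GCA"): (100, 25)},
        )
        scores = normalized_scores(table, pseudocount=0.01)
        assert scores.frame["score"].iloc[0] == pytest.approx(0.26 / 0.2601)

    def test_zero_rate_with_small_pseudocount(self):
        table = crafted_table(
            {"GCA": (100, 10), "CGT": (100, 10)},
            {("GCA", "CGT"): (50, 0), ("CGT", "GCA"): (50, 5)},
        )
        scores = normalized_scores(table, pseudocount=0.001)
        assert scores.frame.set_index("codon1").loc["GCA", "score"] == \
            pytest.approx(0.001 / (0.101 ** 2))

    def test_auto_pseudocount_is_reciprocal_total(self):
        table = crafted_table(
            {"GCA": (150, 50), "CGT": (50, 20)},
            {("GCA", "CGT"): (40, 10)},
        )
        scores = normalized_scores(table, "auto")
        assert scores.pseudocount == pytest.approx(1.0 / 200)

    def test_zero_pseudocount_zero_codon_rate_flagged(self):
        table = crafted_table(
            {"GCA": (100, 0), "CGT": (100, 10)},
            {("GCA", "CGT"): (50, 0)},
        )
        scores = normalized_scores(table, pseudocount=0.0)
        assert np.isnan(scores.frame["score"]).all()

    def test_limit_converges_to_ratio(self):
        table = crafted_table(
            {"GCA": (100, 40), "CGT": (100, 25)},
            {("GCA", "CGT"): (100, 15)},
        )
        target = 0.15 / (0.40 * 0.25)
        errors = []
        for p in (1e-3, 1e-6, 1e-9):
            s = normalized_scores(table, p).frame["score"].iloc[0]
            errors.append(abs(s - target))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-7


def scores_from(pairs_scores):
    frame = pd.DataFrame([
        {"codon1": c1, "codon2": c2, "score": s}
        for (c1, c2), s in pairs_scores.items()
    ])
    return NormalizedScoreTable(pseudocount=0.0, frame=frame, n_excluded=0)


class TestDipeptideZ:
    def test_family_arithmetic(self, code1):
        # one Ala-Ala family with scores {e, e, e^3}: X = {1, 1, 3},
        # mu = 5/3, sample sigma = 2/sqrt(3)
        e = np.e
        scores = scores_from({
            ("GCA", "GCC"): e, ("GCA", "GCG"): e, ("GCA", "GCT"): e ** 3})
        z = dipeptide_zscores(scores, code1)
        x = np.array([1.0, 1.0, 3.0])
        want = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(z["z"], want, atol=1e-12)
        assert z["sigma_dp"].iloc[0] == pytest.approx(2 / np.sqrt(3))

    def test_log_base_invariance(self, code1):
        scores = scores_from({
            ("GCA", "GCC"): 0.7, ("GCA", "GCG"): 1.9, ("GCA", "GCT"): 3.1})
        z = dipeptide_zscores(scores, code1)["z"].to_numpy()
        x10 = np.log10([0.7, 1.9, 3.1])
        z10 = (x10 - x10.mean()) / x10.std(ddof=1)
        np.testing.assert_allclose(z, z10, atol=1e-12)

    def test_all_equal_scores_degenerate(self, code1):
        scores = scores_from({
            ("GCA", "GCC"): 2.0, ("GCA", "GCG"): 2.0})
        z = dipeptide_zscores(scores, code1)
        assert z["z"].tolist() == [0.0, 0.0]
        assert z["degenerate"].all()

    def test_met_trp_single_family_flagged(self, code1):
        scores = scores_from({("ATG", "TGG"): 1.4})
        z = dipeptide_zscores(scores, code1)
        assert z["dipeptide"].iloc[0] == "MW"
        assert z["degenerate"].iloc[0]
        assert z["z"].iloc[0] == 0.0

    def test_family_mean_zero_sigma_one_on_genome(self, code1):
        dataset = generate(SyntheticSpec(n_genes=60, seed=4,
                                         gene_length_range=(80, 200)))
        res = CodonPairConservation.from_alignments(
            to_alignments(dataset), code1).fit()
        z = res.dipeptide_z
        ok = z[~z["degenerate"]]
        stats = ok.groupby("dipeptide")["z"].agg(["mean", "std", "count"])
        stats = stats[stats["count"] > 1]
        np.testing.assert_allclose(stats["mean"], 0.0, atol=1e-9)
        np.testing.assert_allclose(stats["std"], 1.0, atol=1e-9)

    def test_families_partition_sense_pairs(self, code1, code12):
        dataset = generate(SyntheticSpec(n_genes=40, seed=6,
                                         gene_length_range=(60, 150)))
        res = CodonPairConservation.from_alignments(
            to_alignments(dataset), code1).fit()
        z = res.dipeptide_z
        assert len(z) == len(z.drop_duplicates(["codon1", "codon2"]))
        # CTG-containing pairs change family between tables 1 and 12
        table = res.model.table
        z12 = dipeptide_zscores(
            normalized_scores(table, "auto"), code12)
        ctg = z.set_index(["codon1", "codon2"]).loc[("CTG", "GCA")]
        ctg12 = z12.set_index(["codon1", "codon2"]).loc[("CTG", "GCA")]
        assert ctg["dipeptide"] == "LA"
        assert ctg12["dipeptide"] == "SA"


class TestRanking:
    def test_tie_convention(self, code1):
        table = crafted_table(
            {"GCA": (100, 50), "GCC": (100, 50), "GCG": (100, 50),
             "GCT": (100, 50)},
            {("GCA", "GCA"): (10, 9), ("GCA", "GCC"): (10, 5),
             ("GCA", "GCG"): (10, 5), ("GCA", "GCT"): (10, 1)},
        )
        ranks = rank_within_dipeptide(table, code1, by="raw_rate")
        got = dict(zip(ranks["codon2"], ranks["rank"]))
        assert got == {"GCA": 1, "GCC": 2, "GCG": 2, "GCT": 4}

    def test_single_member_family_rank_one(self, code1):
        table = crafted_table(
            {"ATG": (10, 10), "TGG": (10, 10)},
            {("ATG", "TGG"): (5, 2)},
        )
        ranks = rank_within_dipeptide(table, code1, by="raw_rate")
        assert ranks["rank"].tolist() == [1]


class TestCrossComparison:
    def _fit(self, devs):
        frame = pd.DataFrame([
            {"codon1": c1, "codon2": c2, "deviation_sigma": d}
            for (c1, c2), d in devs.items()
        ])
        return PairFitResult(slope=1.0, residual_sigma=0.03, frame=frame,
                             n_excluded=0)

    def test_single_comparison_thresholds(self):
        fits = {"cmp1": self._fit({("CGA", "CGA"): 3.5})}
        out = cross_comparison_consistency(fits, thresholds=(2, 3))
        row = out.loc["CGA-CGA"]
        assert row["above_2_sigma_all"] and row["above_3_sigma_all"]

    def test_mixed_comparisons(self):
        fits = {
            "cmp1": self._fit({("CGA", "CGA"): 3.5, ("GCA", "GCA"): 1.0}),
            "cmp2": self._fit({("CGA", "CGA"): 2.5, ("GCA", "GCA"): 4.0}),
        }
        out = cross_comparison_consistency(fits, thresholds=(2, 3))
        row = out.loc["CGA-CGA"]
        assert row["above_2_sigma_all"] and not row["above_3_sigma_all"]
        assert not out.loc["GCA-GCA", "above_2_sigma_all"]

    def test_incomplete_flag(self):
        fits = {
            "cmp1": self._fit({("CGA", "CGA"): 3.5, ("GCA", "GCA"): 3.2}),
            "cmp2": self._fit({("CGA", "CGA"): 3.6}),
        }
        out = cross_comparison_consistency(fits, thresholds=(3,))
        assert not out.loc["CGA-CGA", "incomplete"]
        assert out.loc["GCA-GCA", "incomplete"]
        # defined comparisons all above threshold still flag
        assert out.loc["GCA-GCA", "above_3_sigma_all"]

    def test_reproducible_across_seeds(self, code1):
        """Pairwise comparisons built from one genome give identical flag
        sets on repeated runs."""
        dataset = generate(SyntheticSpec(
            n_genes=60, seed=12, gene_length_range=(80, 200)))
        alns = to_alignments(dataset)
        def flags():
            fits = {}
            for sp in ("sp1", "sp2"):
                sub = [a.subset(["ref", sp]) for a in alns]
                from paircons import accumulate_conservation
                fits[sp] = fit_origin_line(
                    accumulate_conservation(sub, code1))
            out = cross_comparison_consistency(fits, thresholds=(3,))
            return set(out[out["above_3_sigma_all"]].index)
        assert flags() == flags()


class TestFrameShiftControl:
    def test_identical_alignments_z_zero(self, code1):
        from paircons import CodonAlignment, accumulate_conservation, \
            shifted_frame_conservation
        rng = np.random.default_rng(8)
        sense = [c for c in code1.sense_codons]
        alns = []
        for g in range(5):
            rows = tuple(sense[i] for i in rng.integers(0, 61, 40))
            alns.append(CodonAlignment(
                f"g{g}", "ref", {"ref": rows, "sp1": rows}))
        tables = {0: accumulate_conservation(alns, code1),
                  1: shifted_frame_conservation(alns, 1, code1),
                  2: shifted_frame_conservation(alns, 2, code1)}
        focal = [("CGA", "CGA"), ("GCA", "GCC")]
        out = frame_shift_control(tables, focal, code1)
        present = out[~out["absent"]]
        np.testing.assert_allclose(present["z"], 0.0, atol=1e-9)

    def test_absent_hexamer_flagged(self, code1):
        from paircons import CodonAlignment, accumulate_conservation, \
            shifted_frame_conservation
        rows = ("ATG", "GCA", "CGA")
        aln = CodonAlignment("g", "ref", {"ref": rows, "sp1": rows})
        tables = {0: accumulate_conservation([aln], code1),
                  1: shifted_frame_conservation([aln], 1, code1)}
        out = frame_shift_control(tables, [("AAA", "AAA")], code1)
        assert out["absent"].all()


class TestModelObject:
    def test_summary_and_accessors(self, code1):
        dataset = generate(SyntheticSpec(n_genes=50, seed=3,
                                         gene_length_range=(80, 200)))
        model = CodonPairConservation.from_alignments(
            to_alignments(dataset), code1)
        res = model.fit(k_sigma=3.0)
        text = res.summary()
        assert "slope" in text and f"{res.slope:.4f}" in text
        assert res.params["slope"] == res.slope
        assert 0 < res.rsquared <= 1
        assert set(res.deviations.index) == {
            f"{a}-{b}" for a, b in zip(
                res.fit_result.frame["codon1"],
                res.fit_result.frame["codon2"])}

    def test_normalized_outlier_route_runs(self, code1):
        dataset = generate(SyntheticSpec(n_genes=50, seed=3,
                                         gene_length_range=(80, 200)))
        model = CodonPairConservation.from_alignments(
            to_alignments(dataset), code1)
        res = model.fit(k_sigma=3.0, outlier_route="normalized")
        assert isinstance(res.outliers_above, frozenset)
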