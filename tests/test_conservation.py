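"""Conservation counting versus hand counts and the brute-force comparator."""

import numpy as np
import pytest

from paircons import (
    CodonAlignment,
    accumulate_conservation,
    is_conserved_column,
    local_conservation_profile,
    orf_conservation_rates,
    shifted_frame_conservation,
)
from paircons.codes import CODON_INDEX, CODONS, GAP_CODON
from paircons.conservation import reference_view
from paircons.errors import PairconsError
from paircons.simulate import SyntheticSpec, generate, to_alignments

from _oracles import (
    codon_alignment_to_nt_rows,
    conservation_counts_bruteforce,
)
from conftest import make_random_alignment


def idx(codon):
    return CODON_INDEX[codon]


class TestConservedColumn:
    def test_all_identical(self, toy_alignment):
        flag, codon = is_conserved_column(toy_alignment, 0)
        assert flag and codon == "ATG"

    def test_mismatch(self, toy_alignment):
        flag, codon = is_conserved_column(toy_alignment, 1)
        assert not flag and codon == "GCA"

    def test_gap_breaks_conservation(self):
        aln = CodonAlignment("g", "ref", {
            "ref": ("ATG",), "sp1": (GAP_CODON,)})
        flag, _ = is_conserved_column(aln, 0)
        assert not flag

    def test_reference_gap_errors(self):
        aln = CodonAlignment("g", "ref", {
            "ref": (GAP_CODON,), "sp1": ("ATG",)})
        with pytest.raises(PairconsError):
            is_conserved_column(aln, 0)


class TestAccumulate:
    def test_toy_counts(self, toy_alignment, code1):
        table = accumulate_conservation([toy_alignment], code1)
        assert table.codon_total[idx("ATG")] == 1
        assert table.codon_cons[idx("ATG")] == 1
        assert table.codon_total[idx("GCA")] == 1
        assert table.codon_cons[idx("GCA")] == 0
        assert table.codon_cons[idx("CGA")] == 1
        assert table.pair_total[idx("ATG"), idx("GCA")] == 1
        assert table.pair_cons[idx("ATG"), idx("GCA")] == 0
        assert table.pair_total[idx("GCA"), idx("CGA")] == 1
        assert table.pair_cons[idx("GCA"), idx("CGA")] == 0

    def test_fully_identical_rates_one(self, code1):
        rows = ("ATG", "GCA", "CGA", "TGG")
        aln = CodonAlignment("g", "ref",
                             {"ref": rows, "sp1": rows, "sp2": rows})
        table = accumulate_conservation([aln], code1)
        rates = table.codon_rates
        assert np.all(rates[~np.isnan(rates)] == 1.0)
        prates = table.pair_rates
        assert np.all(prates[~np.isnan(prates)] == 1.0)

    def test_insertion_column_breaks_pair(self, code1):
        """Both flanking codons conserved, but an insertion private to one
        species sits between them: the pair total counts, conserved does
        not."""
        aln = CodonAlignment("g", "ref", {
            "ref": ("ATG", GAP_CODON, "GCA"),
            "sp1": ("ATG", "TTT", "GCA"),
        })
        table = accumulate_conservation([aln], code1)
        assert table.codon_cons[idx("ATG")] == 1
        assert table.codon_cons[idx("GCA")] == 1
        assert table.pair_total[idx("ATG"), idx("GCA")] == 1
        assert table.pair_cons[idx("ATG"), idx("GCA")] == 0
        assert table.n_pairs_interrupted == 1

    def test_total_sums(self, code1):
        rng = np.random.default_rng(0)
        alns = [make_random_alignment(rng, group_id=f"g{i}")
                for i in range(5)]
        table = accumulate_conservation(alns, code1)
        n_sense = sum(
            sum(1 for c in reference_view(a).codons
                if not code1.is_stop(str(c)))
            for a in alns)
        assert table.total_reference_codons == n_sense

    def test_mixed_reference_errors(self, toy_alignment, code1):
        other = CodonAlignment("g2", "sp1", dict(toy_alignment.rows))
        with pytest.raises(PairconsError, match="mixed reference"):
            accumulate_conservation([toy_alignment, other], code1)

    def test_conserved_pair_implies_conserved_codons(self, code1):
        rng = np.random.default_rng(3)
        alns = [make_random_alignment(rng, group_id=f"g{i}")
                for i in range(8)]
        table = accumulate_conservation(alns, code1)
        # a conserved pair needs both member columns conserved, so each
        # codon's conserved count is at least its conserved-pair involvement
        # in any single alignment; check the direct global consequence:
        assert np.all(table.pair_cons <= table.pair_total)
        assert np.all(table.codon_cons <= table.codon_total)

    def test_monotone_in_species(self, code1):
        """Adding a divergent species never increases conserved counts."""
        rng = np.random.default_rng(11)
        alns = [make_random_alignment(rng, n_species=4, group_id=f"g{i}")
                for i in range(6)]
        full = accumulate_conservation(alns, code1)
        reduced = accumulate_conservation(
            [a.subset(["ref", "sp1", "sp2"]) for a in alns], code1)
        assert np.all(full.codon_cons <= reduced.codon_cons)
        assert np.all(full.pair_cons <= reduced.pair_cons)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_random_fixtures(self, offset, code1):
        rng = np.random.default_rng(2024 + offset)
        stops = set(code1.stop_codons)
        for rep in range(6):
            alns = [
                make_random_alignment(
                    rng, n_species=int(rng.integers(2, 5)),
                    n_codons=int(rng.integers(5, 25)),
                    group_id=f"g{rep}_{i}")
                for i in range(int(rng.integers(1, 4)))
            ]
            if offset == 0:
                table = accumulate_conservation(alns, code1)
            else:
                table = shifted_frame_conservation(alns, offset, code1)
            ut, uc, pt, pc = {}, {}, {}, {}
            for aln in alns:
                rows = codon_alignment_to_nt_rows(aln)
                u_t, u_c, p_t, p_c = conservation_counts_bruteforce(
                    rows, "ref", offset, stops)
                for d, src in ((ut, u_t), (uc, u_c), (pt, p_t), (pc, p_c)):
                    for k, v in src.items():
                        d[k] = d.get(k, 0) + v
            for codon in CODONS:
                i = CODON_INDEX[codon]
                assert table.codon_total[i] == ut.get(codon, 0)
                assert table.codon_cons[i] == uc.get(codon, 0)
            got_pt = {
                (CODONS[i], CODONS[j]): int(table.pair_total[i, j])
                for i, j in zip(*np.nonzero(table.pair_total))
            }
            got_pc = {
                (CODONS[i], CODONS[j]): int(table.pair_cons[i, j])
                for i, j in zip(*np.nonzero(table.pair_cons))
            }
            assert got_pt == pt
            assert got_pc == pc


class TestShiftedTokenization:
    def test_offsets(self, code1):
        rows = ("ATG", "GCA", "CGA")
        aln = CodonAlignment("g", "ref", {"ref": rows, "sp1": rows})
        t1 = shifted_frame_conservation([aln], 1, code1)
        assert t1.codon_total[idx("TGG")] == 1
        assert t1.codon_total[idx("CAC")] == 1
        assert t1.codon_total.sum() == 2
        t2 = shifted_frame_conservation([aln], 2, code1)
        assert t2.codon_total[idx("GGC")] == 1
        assert t2.codon_total[idx("ACG")] == 1

    def test_identical_alignment_all_conserved(self, code1):
        rows = tuple(CODONS[i] for i in (0, 17, 33, 60, 5, 21))
        aln = CodonAlignment("g", "ref",
                             {"ref": rows, "sp1": rows, "sp2": rows})
        for offset in (1, 2):
            t = shifted_frame_conservation([aln], offset, code1)
            assert np.array_equal(t.codon_total, t.codon_cons)
            assert np.array_equal(t.pair_total, t.pair_cons)


class TestOrfRates:
    def test_identical_rate_one(self, code1):
        rows = tuple("ATG" for _ in range(100))
        aln = CodonAlignment("g", "ref", {"ref": rows, "sp1": rows})
        (orf,) = orf_conservation_rates([aln])
        assert orf.rate == 1.0
        assert orf.length_codons == 100

    def test_toy_two_thirds(self, toy_alignment):
        (orf,) = orf_conservation_rates([toy_alignment])
        assert orf.conserved_codons == 2
        assert orf.rate == pytest.approx(2 / 3)

    def test_generator_truth(self, code1):
        spec = SyntheticSpec(n_species=4, n_genes=20,
                             gene_length_range=(30, 80),
                             substitution_prob=0.25, seed=9,
                             planted_pairs=())
        dataset = generate(spec)
        alns = to_alignments(dataset)
        got = {o.orf_id: (o.length_codons, o.conserved_codons)
               for o in orf_conservation_rates(alns)}
        assert got == dataset.truth.orf_conserved


class TestLocalProfile:
    def test_all_conserved_constant(self):
        rows = tuple("GCA" for _ in range(20))
        aln = CodonAlignment("g", "ref", {"ref": rows, "sp1": rows})
        profile = local_conservation_profile(aln, window=5)
        assert np.all(profile == 1.0)

    def test_alternating_window_two(self):
        ref = tuple("GCA" if i % 2 == 0 else "CGT" for i in range(7))
        other = tuple("GCA" if i % 2 == 0 else "CGA" for i in range(7))
        aln = CodonAlignment("g", "ref", {"ref": ref, "sp1": other})
        profile = local_conservation_profile(aln, window=2)
        assert set(np.round(profile, 6)) <= {0.0, 0.5, 1.0}
        assert 0.5 in set(profile)

    def test_window_equal_orf_length_is_rate(self, toy_alignment):
        profile = local_conservation_profile(toy_alignment, window=3)
        assert profile.tolist() == [pytest.approx(2 / 3)]
        wide = local_conservation_profile(toy_alignment, window=10)
        assert wide.tolist() == [pytest.approx(2 / 3)]
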