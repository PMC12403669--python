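"""Yates-corrected chi-square tests and syn/nonsyn site counting."""

import itertools
import textwrap

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

from mastat import (
    chisq_contingency,
    codon_syn_nonsyn_fractions,
    count_syn_nonsyn_sites,
    yates_2x2_test,
    yates_gof_test,
)
from mastat.selection import cds_from_gff
from tests.conftest import NONSYN_SITES, SYN_SITES


def _cellwise_yates_2x2(a, b, c, d):
    """Independent oracle: Yates statistic summed cell by cell."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((np.maximum(np.abs(obs - expected) - 0.5, 0)) ** 2
                  / expected).sum())


class TestGoodnessOfFit:
    def test_control_nonsyn_syn_ratio(self):
        t = yates_gof_test(5, 4, NONSYN_SITES, SYN_SITES)
        assert round(t.statistic, 2) == 1.67
        assert round(t.p_value, 2) == 0.20
        assert t.df == 1

    def test_treatment_nonsyn_syn_ratio(self):
        t = yates_gof_test(11, 2, NONSYN_SITES, SYN_SITES)
        assert round(t.statistic, 2) == 0.03
        assert round(t.p_value, 2) == 0.86

    def test_perfect_fit_gives_zero(self):
        # observed exactly proportional to sites: correction floors at 0
        t = yates_gof_test(787, 213, 787.0, 213.0)
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_corrected_never_exceeds_pearson(self):
        for obs_n, obs_s in [(5, 4), (11, 2), (100, 3), (1, 1)]:
            n = obs_n + obs_s
            e_n = n * NONSYN_SITES / (NONSYN_SITES + SYN_SITES)
            pearson = (obs_n - e_n) ** 2 / e_n + \
                (obs_s - (n - e_n)) ** 2 / (n - e_n)
            t = yates_gof_test(obs_n, obs_s, NONSYN_SITES, SYN_SITES)
            assert t.statistic <= pearson + 1e-12

    def test_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            yates_gof_test(0, 0, 1.0, 1.0)


class TestTwoByTwo:
    def test_between_group_comparison(self):
        t = yates_2x2_test(5, 4, 11, 2)
        assert round(t.statistic, 2) == 1.04
        assert round(t.p_value, 2) == 0.31

    def test_balanced_table_gives_zero(self):
        t = yates_2x2_test(10, 10, 10, 10)
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_shortcut_equals_cellwise_formula(self):
        assert yates_2x2_test(5, 4, 11, 2).statistic == pytest.approx(
            _cellwise_yates_2x2(5, 4, 11, 2))

    def test_shortcut_equals_cellwise_on_random_tables(self):
        """The margin-product shortcut == cell-wise Yates, 1,000 tables."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 60, size=4)
            assert yates_2x2_test(a, b, c, d).statistic == pytest.approx(
                _cellwise_yates_2x2(a, b, c, d), abs=1e-9)

    def test_invariant_under_simultaneous_swap(self):
        t1 = yates_2x2_test(5, 4, 11, 2)
        t2 = yates_2x2_test(2, 11, 4, 5)  # both rows and both columns swapped
        assert t1.statistic == pytest.approx(t2.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            yates_2x2_test(0, 0, 5, 3)


class TestContingency:
    def test_2x2_with_yates_delegates(self):
        t = chisq_contingency([[5, 4], [11, 2]], yates=True)
        assert t.statistic == pytest.approx(
            yates_2x2_test(5, 4, 11, 2).statistic)

    def test_identical_rows_give_zero(self):
        t = chisq_contingency([[7, 3], [7, 3], [7, 3]])
        assert t.statistic == pytest.approx(0.0)
        assert t.df == 2

    def test_random_3x2_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        table = rng.integers(5, 50, size=(3, 2))
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        t = chisq_contingency(table)
        assert t.statistic == pytest.approx(brute)
        assert t.df == 2


ALL_SENSE_CODONS = [
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in CodonTable.unambiguous_dna_by_id[1].stop_codons
]


def _brute_force_codon_sites(codon):
    """Independent oracle: enumerate the nine changes via Bio.Seq.translate."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant_aa = str(Seq(codon[:pos] + b + codon[pos + 1:]).translate())
            if mutant_aa == aa:  # a stop ('*') never equals a sense residue
                syn += 1
    return 3 - syn / 3, syn / 3


class TestSiteCounting:
    @pytest.mark.parametrize("codon,nonsyn,syn", [
        ("TTT", 8 / 3, 1 / 3),  # Phe: only third-position TTC is synonymous
        ("TGG", 3.0, 0.0),      # Trp: every change is nonsynonymous
        ("GGG", 2.0, 1.0),      # Gly: third position four-fold degenerate
    ])
    def test_reference_codons(self, codon, nonsyn, syn):
        ns, s = codon_syn_nonsyn_fractions(codon)
        assert ns == pytest.approx(nonsyn)
        assert s == pytest.approx(syn)

    @pytest.mark.parametrize("codon", ALL_SENSE_CODONS)
    def test_every_sense_codon_contributes_three_sites(self, codon):
        ns, s = codon_syn_nonsyn_fractions(codon)
        assert ns + s == pytest.approx(3.0)

    def test_all_sense_codons_match_brute_force(self):
        for codon in ALL_SENSE_CODONS:
            assert codon_syn_nonsyn_fractions(codon) == pytest.approx(
                _brute_force_codon_sites(codon))

    def test_cds_totals_sum_codon_contributions(self):
        ns, s = count_syn_nonsyn_sites(["TTTGGG"])
        assert ns == pytest.approx(8 / 3 + 2)
        assert s == pytest.approx(1 / 3 + 1)

    def test_terminal_stop_skipped(self):
        with_stop = count_syn_nonsyn_sites(["TTTTAA"])
        without = count_syn_nonsyn_sites(["TTT"])
        assert with_stop == pytest.approx(without)

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            count_syn_nonsyn_sites(["TTTA"])

    def test_internal_stop_names_codon(self):
        with pytest.raises(ValueError, match="codon 1"):
            count_syn_nonsyn_sites(["TTTTAATTT"])

    def test_stop_creating_changes_can_be_excluded(self):
        # TAT (Tyr): TAA/TAG changes create stops
        default = codon_syn_nonsyn_fractions("TAT")
        excl = codon_syn_nonsyn_fractions("TAT", stops_as_nonsyn=False)
        assert default[0] + default[1] == pytest.approx(3.0)
        assert excl[1] > default[1]  # renormalised syn fraction grows


class TestGffExtraction:
    def test_stitched_strand_aware_cds(self, tmp_path):
        fasta = tmp_path / "g.fa"
        # gene1 (+): CDS 1-6 = ATGGGG; gene2 (-): CDS 11-16 revcomp
        fasta.write_text(">chr1\nATGGGGCCCCAAATTT\n")
        gff = tmp_path / "a.gff3"
        gff.write_text(textwrap.dedent("""\
            ##gff-version 3
            chr1\tsrc\tmRNA\t1\t6\t.\t+\t.\tID=t1
            chr1\tsrc\tCDS\t1\t3\t.\t+\t0\tID=c1;Parent=t1
            chr1\tsrc\tCDS\t4\t6\t.\t+\t0\tID=c2;Parent=t1
            chr1\tsrc\tmRNA\t11\t16\t.\t-\t.\tID=t2
            chr1\tsrc\tCDS\t11\t16\t.\t-\t0\tID=c3;Parent=t2
            """))
        seqs = cds_from_gff(gff, fasta)
        # minus-strand CDS is bases 11-16 ("AAATTT"), reverse-complemented
        assert seqs == ["ATGGGG", str(Seq("AAATTT").reverse_complement())]
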