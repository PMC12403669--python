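"""Six-class spectra, ts/tv, A/T-direction bias, In/Del ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mastat import (
    ExperimentGroup,
    GenomeComposition,
    MALine,
    MutationRecord,
    at_bias,
    conditional_spectrum_rates,
    ins_del_ratio,
    spectrum_counts,
    summarize_spectrum,
    ts_tv_ratio,
)
from mastat.records import SPECTRUM_CLASSES


def _bps(line_id, pos, ref, alt):
    return MutationRecord(line_id, "chr1", pos, ref, alt)


class TestSpectrumCounts:
    def test_strand_collapsed_tally(self):
        muts = [_bps("L1", 1, "C", "T"), _bps("L1", 2, "G", "A"),
                _bps("L1", 3, "A", "G")]
        counts = spectrum_counts(muts)
        assert counts["G:C->A:T"] == 2
        assert counts["A:T->G:C"] == 1
        assert sum(counts.values()) == 3

    def test_empty_set_is_all_zero(self):
        assert set(spectrum_counts([]).values()) == {0}

    def test_non_bps_records_ignored(self):
        muts = [_bps("L1", 1, "C", "T"),
                MutationRecord("L1", "chr1", 2, "A", "AC")]
        assert sum(spectrum_counts(muts).values()) == 1

    def test_multinomial_recovery(self):
        """10,000 draws from known class probabilities land within 3 sigma."""
        probs = np.array([0.22, 0.06, 0.06, 0.45, 0.14, 0.07])
        rng = np.random.default_rng(5)
        n = 10_000
        draws = rng.choice(len(SPECTRUM_CLASSES), size=n, p=probs)
        ref_alt = {"A:T->G:C": ("A", "G"), "A:T->T:A": ("A", "T"),
                   "A:T->C:G": ("A", "C"), "G:C->A:T": ("G", "A"),
                   "G:C->T:A": ("G", "T"), "G:C->C:G": ("G", "C")}
        muts = [_bps("L1", i + 1, *ref_alt[SPECTRUM_CLASSES[d]])
                for i, d in enumerate(draws)]
        counts = spectrum_counts(muts)
        for cls, p in zip(SPECTRUM_CLASSES, probs):
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - n * p) <= 3 * sigma


class TestConditionalRates:
    def _group(self, per_line_muts, callable_sites=None, divisions=100.0):
        lines, muts = [], []
        for i, line_muts in enumerate(per_line_muts, start=1):
            lid = f"L{i}"
            lines.append(MALine(lid, "g", total_divisions=divisions,
                                callable_sites=callable_sites))
            muts.extend(
                _bps(lid, 1000 * i + j, ref, alt)
                for j, (ref, alt) in enumerate(line_muts)
            )
        return ExperimentGroup(name="g", lines=lines, mutations=muts)

    def test_single_line_rate_and_zero_sem(self):
        comp = GenomeComposition(at_sites=2_000_000, gc_sites=1_000_000)
        group = self._group([[("G", "A")]])
        rates, sem = conditional_spectrum_rates(group, comp)
        assert rates["G:C->A:T"] == pytest.approx(1e-8)  # 1/(1e6 * 100)
        assert all(s == 0.0 for s in sem.values())

    def test_identical_lines_have_zero_sem(self):
        comp = GenomeComposition(at_sites=2_000_000, gc_sites=1_000_000)
        group = self._group([[("G", "A")], [("G", "A")]])
        _, sem = conditional_spectrum_rates(group, comp)
        assert all(s == 0.0 for s in sem.values())

    def test_callable_fraction_scales_origin_sites(self):
        comp = GenomeComposition(at_sites=2_000_000, gc_sites=2_000_000)
        group = self._group([[("G", "A")]], callable_sites=2_000_000)
        rates, _ = conditional_spectrum_rates(group, comp)
        # half the genome callable -> origin sites halved, rate doubled
        assert rates["G:C->A:T"] == pytest.approx(1 / (1_000_000 * 100))

    def test_pooled_consistency(self):
        """Sum of class rate x origin sites x divisions recovers the count."""
        comp = GenomeComposition(at_sites=3_000_000, gc_sites=1_500_000)
        group = self._group(
            [[("G", "A"), ("A", "G"), ("C", "G"), ("T", "A")]])
        rates, _ = conditional_spectrum_rates(group, comp)
        total = sum(
            rates[cls] * (comp.at_sites if cls.startswith("A:T")
                          else comp.gc_sites) * 100.0
            for cls in SPECTRUM_CLASSES
        )
        assert total == pytest.approx(4.0)

    def test_simulated_group_recovers_class_rates(self):
        """50-line synthetic group: class-rate means near the truth."""
        from mastat.simulate import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_lines_control=50, n_lines_treatment=1,
                               mu_bps=3e-10, mu_indel=0.0, mu_sv=0.0, seed=11)
        control, _, comp, _ = simulate_experiment(cfg)
        rates, sem = conditional_spectrum_rates(control, comp)
        g_per_line = cfg.callable_sites * cfg.total_divisions
        for cls, p in zip(SPECTRUM_CLASSES, cfg.spectrum_probs):
            origin = comp.at_sites if cls.startswith("A:T") else comp.gc_sites
            truth = cfg.mu_bps * p * cfg.genome_length / origin
            tol = max(3 * sem[cls], 0.5 * truth)
            assert rates[cls] == pytest.approx(truth, abs=tol)


class TestRatios:
    @pytest.mark.parametrize("ts,tv,expected", [
        (12, 6, 2.00), (1, 1, 1.0), (15, 9, 1.67)])
    def test_ts_tv(self, ts, tv, expected):
        counts = {"A:T->G:C": ts, "A:T->T:A": tv}
        assert round(ts_tv_ratio(counts), 2) == expected

    def test_ts_tv_no_transversions_is_flagged_infinite(self):
        assert math.isinf(ts_tv_ratio({"A:T->G:C": 3, "G:C->A:T": 2}))

    def test_at_bias_hand_arithmetic(self):
        comp = GenomeComposition(at_sites=8_000_000, gc_sites=4_000_000)
        counts = {"G:C->A:T": 4, "G:C->T:A": 2, "A:T->G:C": 1, "A:T->C:G": 1}
        assert at_bias(counts, comp) == pytest.approx(6.0)

    def test_at_bias_equal_rates_is_one(self):
        comp = GenomeComposition(at_sites=1_000_000, gc_sites=1_000_000)
        counts = {"G:C->A:T": 3, "A:T->G:C": 3}
        assert at_bias(counts, comp) == pytest.approx(1.0)

    def test_at_bias_equal_composition_counts_4_vs_2(self):
        comp = GenomeComposition(at_sites=1_000_000, gc_sites=1_000_000)
        counts = {"G:C->A:T": 4, "A:T->G:C": 2}
        assert at_bias(counts, comp) == pytest.approx(2.0)

    @given(st.integers(min_value=1, max_value=4))
    def test_at_bias_invariant_under_doubling(self, factor):
        comp1 = GenomeComposition(at_sites=2_000_000, gc_sites=1_000_000)
        comp2 = GenomeComposition(at_sites=2_000_000 * factor,
                                  gc_sites=1_000_000 * factor)
        counts1 = {"G:C->A:T": 5, "G:C->T:A": 1, "A:T->G:C": 2, "A:T->C:G": 1}
        counts2 = {k: v * factor for k, v in counts1.items()}
        assert at_bias(counts2, comp2) == pytest.approx(
            at_bias(counts1, comp1))

    @pytest.mark.parametrize("ins,dele,expected", [
        (21, 3, 7.00), (28, 2, 14.00), (5, 5, 1.0)])
    def test_ins_del(self, ins, dele, expected):
        muts = [MutationRecord("L1", "c", i + 1, "A", "AC")
                for i in range(ins)]
        muts += [MutationRecord("L1", "c", 1000 + i, "AC", "A")
                 for i in range(dele)]
        assert ins_del_ratio(muts) == pytest.approx(expected)

    def test_ins_del_no_deletions_is_flagged_infinite(self):
        muts = [MutationRecord("L1", "c", 1, "A", "AC")]
        assert math.isinf(ins_del_ratio(muts))


class TestSummary:
    def test_curated_control_summary(self, curated_control, composition):
        s = summarize_spectrum(curated_control, composition)
        assert round(s.ts_tv, 2) == 2.00
        assert round(s.ins_del, 2) == 7.00
        assert sum(s.class_counts.values()) == 18
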