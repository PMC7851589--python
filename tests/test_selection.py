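"""Codon-counting dN/dS estimation and its summaries."""

import math

import numpy as np
import pytest

from oriscan.blocks import GeneSegment
from oriscan.selection import (
    SelectionRecord,
    _CODON_TABLE,
    codon_differences,
    codon_sites,
    compute_dn_ds,
    fit_selection_regressions,
    jukes_cantor,
    omega_outlier_filter,
    pairwise_ng86,
    weighted_genome_average,
)
from oriscan.replicon import Replicon, assign_terminus

from oracles import enumerate_codon_paths

ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def make_segment(seqs, start=1):
    n = len(next(iter(seqs.values())))
    return GeneSegment(
        id="seg1",
        seqs=dict(seqs),
        position_maps={t: np.arange(start, start + n) for t in seqs},
        strands={t: "+" for t in seqs},
        codon_pos=np.tile([1, 2, 3], n // 3).astype(np.int8),
    )


class TestCodonCounting:
    def test_site_counts_sum_to_three_for_sense_codons(self):
        for codon in ALL_CODONS:
            s, n = codon_sites(codon)
            if _CODON_TABLE[codon] == "*":
                assert (s, n) == (0.0, 0.0)
            else:
                assert s + n == pytest.approx(3.0)
                assert 0.0 <= s <= 3.0

    def test_fourfold_degenerate_third_position(self):
        s, _ = codon_sites("GCT")  # alanine: third position fully synonymous
        assert s == pytest.approx(1.0)

    def test_methionine_has_no_synonymous_sites(self):
        s, _ = codon_sites("ATG")
        assert s == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "pair",
        [("GCT", "GCC"), ("AAA", "AGA"), ("TTT", "GAC"), ("ATG", "TGG"), ("TCG", "AGT")],
    )
    def test_differences_match_path_enumeration_oracle(self, pair):
        got = codon_differences(*pair)
        expected = enumerate_codon_paths(*pair, _CODON_TABLE)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_differences_exhaustive_over_codon_pairs(self):
        """Every sense-codon pair agrees with the independent path oracle."""
        sense = [c for c in ALL_CODONS if _CODON_TABLE[c] != "*"]
        for c1 in sense[::3]:
            for c2 in sense[::5]:
                got = codon_differences(c1, c2)
                exp = enumerate_codon_paths(c1, c2, _CODON_TABLE)
                assert got == pytest.approx(exp, abs=1e-12), (c1, c2)


class TestPairwiseNG86:
    def test_identical_sequences_have_zero_rates(self):
        dn, ds = pairwise_ng86("GCTGCTGCT", "GCTGCTGCT")
        assert (dn, ds) == (0.0, 0.0)

    def test_single_synonymous_change_hand_computed(self):
        # GCT->GCC: one synonymous difference in 9 bp of alanine codons
        seq1, seq2 = "GCTGCTGCT", "GCCGCTGCT"
        dn, ds = pairwise_ng86(seq1, seq2)
        S = 3.0  # one fully synonymous third position per GCx codon
        pS = 1.0 / S
        assert ds == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3))
        assert dn == 0.0

    def test_single_nonsynonymous_change(self):
        # AAA (K) -> GAA (E): nonsynonymous first-position change
        dn, ds = pairwise_ng86("AAAGCTGCT", "GAAGCTGCT")
        assert ds == 0.0 and dn > 0

    def test_saturated_pair_returns_none(self):
        # maximally divergent codons drive p beyond the JC domain
        assert pairwise_ng86("AAAAAAAAA", "CCCCCCCCC") is None

    def test_jukes_cantor_domain(self):
        assert jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError):
            jukes_cantor(0.75)


class TestComputeDnDs:
    def test_three_taxon_pairwise_mean(self):
        seqs = {"a": "AAAGCTGCT", "b": "AAAGCTGCT", "c": "GAAGCTGCT"}
        rec = compute_dn_ds(make_segment(seqs))
        pair = pairwise_ng86(seqs["a"], seqs["c"])
        assert rec.dn == pytest.approx((0.0 + pair[0] + pair[0]) / 3)
        assert rec.ds == 0.0
        assert rec.omega is None  # dS = 0 leaves omega undefined

    def test_identical_segment_zero_rates_undefined_omega(self):
        rec = compute_dn_ds(make_segment({t: "GCTGCTGCT" for t in "ab"}))
        assert rec.dn == 0.0 and rec.ds == 0.0 and rec.omega is None

    def test_distance_anchored_at_reference_midpoint(self):
        rep = assign_terminus(Replicon(name="r", length=10_000, origin=1))
        rec = compute_dn_ds(make_segment({t: "GCTGCTGCT" for t in "ab"}, start=101), replicon=rep)
        assert rec.distance == pytest.approx(104)  # midpoint of 101..109 is 105, distance 104


class TestOmegaOutlierFilter:
    def _records(self, omegas):
        return [
            SelectionRecord(f"s{i}", 100, dn=o * 0.1, ds=0.1, omega=o)
            for i, o in enumerate(omegas)
        ]

    def test_extreme_omega_record_fully_excluded(self):
        recs = self._records([0.01, 0.02, 0.03, 0.04, 0.05, 9.0])
        omega_outlier_filter(recs)
        assert [r.outlier for r in recs] == [False] * 5 + [True]
        ds_bar, dn_bar, _ = weighted_genome_average(recs)
        assert ds_bar == pytest.approx(0.1)
        assert dn_bar == pytest.approx(np.mean([0.001, 0.002, 0.003, 0.004, 0.005]))

    def test_equal_omegas_nothing_excluded(self):
        recs = self._records([0.5] * 6)
        omega_outlier_filter(recs)
        assert not any(r.outlier for r in recs)

    def test_undefined_omega_never_flagged(self):
        recs = self._records([0.1, 0.2, 0.3, 0.4])
        recs.append(SelectionRecord("szero", 100, dn=0.5, ds=0.0, omega=None))
        omega_outlier_filter(recs)
        assert recs[-1].outlier is False


class TestWeightedAverage:
    def test_length_weighting(self):
        recs = [
            SelectionRecord("a", 100, dn=0.02, ds=0.1, omega=0.2),
            SelectionRecord("b", 34, dn=0.06, ds=0.1, omega=0.6),
        ]
        # weights 300 and 102 bp
        ds_bar, dn_bar, omega_bar = weighted_genome_average(recs)
        assert dn_bar == pytest.approx((0.02 * 300 + 0.06 * 102) / 402)

    def test_single_record_is_its_own_average(self):
        recs = [SelectionRecord("a", 50, dn=0.01, ds=0.2, omega=0.05)]
        assert weighted_genome_average(recs) == (0.2, 0.01, 0.05)

    def test_ds_zero_record_kept_for_rates_dropped_from_omega(self):
        recs = [
            SelectionRecord("a", 100, dn=0.03, ds=0.1, omega=0.3),
            SelectionRecord("b", 100, dn=0.03, ds=0.0, omega=None),
        ]
        ds_bar, dn_bar, omega_bar = weighted_genome_average(recs)
        assert dn_bar == pytest.approx(0.03)
        assert ds_bar == pytest.approx(0.05)
        assert omega_bar == pytest.approx(0.3)  # only the defined-omega record

    def test_doubling_lengths_leaves_means_unchanged(self):
        recs = [
            SelectionRecord("a", 100, dn=0.01, ds=0.2, omega=0.05),
            SelectionRecord("b", 200, dn=0.04, ds=0.1, omega=0.4),
        ]
        doubled = [
            SelectionRecord("a", 200, dn=0.01, ds=0.2, omega=0.05),
            SelectionRecord("b", 400, dn=0.04, ds=0.1, omega=0.4),
        ]
        assert weighted_genome_average(recs) == weighted_genome_average(doubled)


class TestSelectionRegressions:
    def test_all_records_at_one_distance_skipped(self):
        recs = [
            SelectionRecord(f"s{i}", 100, dn=0.01, ds=0.1, omega=0.1, distance=5000.0)
            for i in range(5)
        ]
        assert fit_selection_regressions(recs, window_widths=()) == []

    def test_linear_ds_gradient_recovered(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(50):
            d = 1000.0 * i
            ds = 0.01 + 1e-6 * d + rng.normal(0, 1e-4)
            recs.append(
                SelectionRecord(f"s{i}", 100, dn=0.001, ds=ds, omega=0.001 / ds, distance=d)
            )
        fits = fit_selection_regressions(recs, window_widths=())
        ds_fit = next(r for r in fits if r.metadata["response"] == "ds")
        assert ds_fit.coefficient == pytest.approx(1e-6, rel=0.05)
        assert ds_fit.p_value < 1e-6
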