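import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplistr.panel import MotifBlock
from amplistr.simulate import TruthAllele, build_allele_sequence
from amplistr.strtyping import (ParseError, assign_reads_to_loci, bracketed_name,
                                build_inner_sequence, ce_allele_number,
                                detect_flank_variants, parse_repeat_structure,
                                report_sequence_alleles)

from conftest import make_str_locus


class TestCeAlleleNumber:
    @pytest.mark.parametrize("blocks,counts,motif_len,net,expected", [
        # five 5-base units with a 13 bp flanking deletion
        ((MotifBlock("AAAGA"),), (5,), 5, -13, "2.2"),
        # eighteen 4-base units with a 3 bp flanking deletion
        ((MotifBlock("AAGA"),), (18,), 4, -3, "17.1"),
        # fourteen units plus a 2-base partial block
        ((MotifBlock("AAGG"), MotifBlock("AG", 0, 1, "partial")),
         (14, 1), 4, 0, "14.2"),
        # plain integer allele
        ((MotifBlock("AGAT"),), (5,), 4, 0, "5"),
        # intervening block ignored by the CE count
        ((MotifBlock("AAGA"), MotifBlock("GAAAGGA", 0, 1, "none"),
          MotifBlock("AAGA")), (3, 1, 14), 4, 0, "17"),
    ])
    def test_designation(self, blocks, counts, motif_len, net, expected):
        assert ce_allele_number(blocks, counts, motif_len, net) == expected

    def test_negative_adjusted_length_rejected(self):
        with pytest.raises(ValueError):
            ce_allele_number((MotifBlock("AGAT"),), (2,), 4, -20)


class TestParseRepeatStructure:
    def test_printed_compound_structure_unit_count(self, panel):
        # [TCTA]6 [TCTG]5 [TCTA]3 TA [TCTA]3 TCA [TCTA]2 TCCATA [TCTA]8 -> 27
        d21 = panel.str_locus("D21S11")
        inner = ("TCTA" * 6 + "TCTG" * 5 + "TCTA" * 3 + "TA" + "TCTA" * 3
                 + "TCA" + "TCTA" * 2 + "TCCATA" + "TCTA" * 8)
        counts, units = parse_repeat_structure(inner, d21)
        assert units == 27
        assert counts == (6, 5, 3, 1, 3, 1, 2, 1, 8)

    def test_two_block_structure(self, panel):
        d12 = panel.str_locus("D12S391")
        counts, units = parse_repeat_structure("AGAT" * 12 + "AGAC" * 9, d12)
        assert counts == (12, 9)
        assert units == 21

    def test_single_block(self):
        locus = make_str_locus(motif="TCTA")
        counts, units = parse_repeat_structure("TCTA" * 5, locus)
        assert counts == (5,) and units == 5

    def test_undecomposable_sequence_raises(self):
        locus = make_str_locus(motif="TCTA")
        with pytest.raises(ParseError):
            parse_repeat_structure("TCTA" * 3 + "GG", locus)
        with pytest.raises(ParseError):
            parse_repeat_structure("", locus)

    def test_greedy_matches_exhaustive_oracle_on_toy_structures(self):
        """For short sequences, the greedy parser must agree with
        exhaustive decomposition whenever the structure is unambiguous,
        and pick the largest-earlier-block solution on ties."""
        blocks = (MotifBlock("AG", 0, 6), MotifBlock("CT", 0, 6))

        def exhaustive(seq):
            sols = []
            for a, b in itertools.product(range(7), repeat=2):
                if "AG" * a + "CT" * b == seq:
                    sols.append((a, b))
            return sols

        rng = np.random.default_rng(5)
        locus = make_str_locus(structure=blocks, canonical_motif_len=2, hi=6)
        for _ in range(50):
            a, b = rng.integers(0, 7, size=2)
            seq = "AG" * int(a) + "CT" * int(b)
            sols = exhaustive(seq)
            if not seq:
                continue
            counts, _units = parse_repeat_structure(seq, locus)
            assert tuple(counts) in sols
            assert tuple(counts) == max(sols)  # greedy prefers earlier blocks


class TestAssignment:
    def test_exact_flanks_assigned(self, toy_panel):
        locus = toy_panel.str_loci[0]
        read = locus.upstream_flank + "AGAT" * 8 + locus.downstream_flank
        groups, unassigned = assign_reads_to_loci([read], toy_panel)
        assert unassigned == 0
        assert groups[locus.name].total_reads == 1

    def test_flank_budget_enforced(self, toy_panel):
        locus = toy_panel.str_loci[0]
        up = list(locus.upstream_flank)
        for pos in (2, 6, 10, 14):  # four substitutions, budget is three
            up[pos] = "A" if up[pos] != "A" else "C"
        read = "".join(up) + "AGAT" * 8 + locus.downstream_flank
        groups, unassigned = assign_reads_to_loci([read], toy_panel)
        assert unassigned == 1
        assert groups[locus.name].total_reads == 0

    def test_elevated_budget_recovers_read(self, toy_panel):
        # same four-substitution flank accepted once the per-locus budget
        # is raised, as needed for error-prone flanks
        locus = make_str_locus(max_flank_mismatches=5)
        from amplistr.panel import PanelConfig
        p = PanelConfig(name="x", str_loci=[locus])
        up = list(locus.upstream_flank)
        for pos in (2, 6, 10, 14):
            up[pos] = "A" if up[pos] != "A" else "C"
        read = "".join(up) + "AGAT" * 8 + locus.downstream_flank
        groups, unassigned = assign_reads_to_loci([read], p)
        assert unassigned == 0
        assert groups[locus.name].total_reads == 1

    def test_empty_input(self, toy_panel):
        groups, unassigned = assign_reads_to_loci([], toy_panel)
        assert unassigned == 0
        assert all(g.total_reads == 0 for g in groups.values())

    def test_counted_pairs_collapse(self, toy_panel):
        locus = toy_panel.str_loci[0]
        read = locus.upstream_flank + "AGAT" * 6 + locus.downstream_flank
        groups, _ = assign_reads_to_loci([(read, 250)], toy_panel)
        assert groups[locus.name].total_reads == 250


class TestFlankVariants:
    def test_identity_gives_no_variants(self):
        assert detect_flank_variants("ACGTACGT", "ACGTACGT", 100, "upstream") == []

    def test_penta_d_style_deletion_span(self, panel):
        # 13 bp deletion immediately upstream of the repeat region
        pd = panel.str_locus("PentaD")
        allele = TruthAllele(
            (5,), (("deletion", "upstream", len(pd.upstream_flank) - 13, 13),))
        read = build_allele_sequence(pd, allele)
        groups, unassigned = assign_reads_to_loci([(read, 50)], panel)
        assert unassigned == 0
        alleles = report_sequence_alleles(groups["PentaD"], pd, panel)
        assert len(alleles) == 1
        assert alleles[0].ce_label == "2.2"
        (variant,) = alleles[0].flank_variants
        assert (variant.kind, variant.ref_start, variant.ref_end) == \
            ("deletion", 45056073, 45056085)

    def test_dxs10135_downstream_deletion(self, panel):
        dx = panel.str_locus("DXS10135")
        allele = TruthAllele((3, 1, 14, 1), (("deletion", "downstream", 13, 3),))
        read = build_allele_sequence(dx, allele)
        groups, _ = assign_reads_to_loci([(read, 50)], panel)
        alleles = report_sequence_alleles(groups["DXS10135"], dx, panel)
        assert alleles[0].ce_label == "17.1"
        (variant,) = alleles[0].flank_variants
        assert (variant.ref_start, variant.ref_end) == (9306454, 9306456)

    def test_substitution_downstream_of_repeat(self, panel):
        # a SNP four bases downstream of the repeat region is reported at
        # its genomic position
        d5 = panel.str_locus("D5S818")
        alt = "A" if d5.downstream_flank[3] != "A" else "G"
        allele = TruthAllele((10,), (("substitution", "downstream", 3, alt),))
        read = build_allele_sequence(d5, allele)
        groups, _ = assign_reads_to_loci([(read, 50)], panel)
        alleles = report_sequence_alleles(groups["D5S818"], d5, panel)
        (variant,) = alleles[0].flank_variants
        assert variant.kind == "substitution"
        assert variant.ref_start == d5.ref_end + 4
        assert variant.observed == alt

    def test_heterozygote_with_flank_snp_gives_distinct_sequence_alleles(
            self, panel):
        # two STR alleles x a flank substitution on one haplotype ->
        # distinct SNP-STR sequence alleles
        d1 = panel.str_locus("D1S1656")
        alt = "A" if d1.downstream_flank[5] != "A" else "G"
        plain = TruthAllele((5, 0, 8))
        variant = TruthAllele((5, 0, 10), (("substitution", "downstream", 5, alt),))
        reads = [(build_allele_sequence(d1, plain), 500),
                 (build_allele_sequence(d1, variant), 480)]
        groups, _ = assign_reads_to_loci(reads, panel)
        alleles = report_sequence_alleles(groups["D1S1656"], d1, panel)
        assert len(alleles) == 2
        variant_sets = [a.flank_variants for a in alleles]
        assert sum(1 for v in variant_sets if v) == 1


class TestReporting:
    def test_one_percent_rule_is_strict(self, toy_panel):
        locus = toy_panel.str_loci[0]
        main = locus.upstream_flank + "AGAT" * 8 + locus.downstream_flank
        minor_in = locus.upstream_flank + "AGAT" * 7 + locus.downstream_flank
        minor_out = locus.upstream_flank + "AGAT" * 6 + locus.downstream_flank
        reads = [(main, 9800), (minor_in, 101), (minor_out, 99)]
        groups, _ = assign_reads_to_loci(reads, toy_panel)
        assert groups[locus.name].total_reads == 10000
        alleles = report_sequence_alleles(groups[locus.name], locus, toy_panel)
        reported = {a.counts[0] for a in alleles}
        assert reported == {8, 7}  # 101 > 1% reported, 99 <= 1% suppressed

    def test_fractions_sum_to_at_most_one(self, toy_panel):
        locus = toy_panel.str_loci[0]
        reads = [(locus.upstream_flank + "AGAT" * k + locus.downstream_flank, n)
                 for k, n in ((8, 600), (7, 300), (6, 100))]
        groups, _ = assign_reads_to_loci(reads, toy_panel)
        alleles = report_sequence_alleles(groups[locus.name], locus, toy_panel)
        total = sum(a.fraction_of_locus for a in alleles)
        assert total <= 1.0 + 1e-12
        assert all(a.fraction_of_locus >
                   toy_panel.thresholds.reporting_fraction for a in alleles)

    def test_sorted_by_descending_reads(self, toy_panel):
        locus = toy_panel.str_loci[0]
        reads = [(locus.upstream_flank + "AGAT" * k + locus.downstream_flank, n)
                 for k, n in ((6, 100), (8, 600), (7, 300))]
        groups, _ = assign_reads_to_loci(reads, toy_panel)
        alleles = report_sequence_alleles(groups[locus.name], locus, toy_panel)
        counts = [a.read_count for a in alleles]
        assert counts == sorted(counts, reverse=True)


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=57), st.data())
def test_naming_round_trip_over_panel(panel_index, data):
    """build -> assign -> parse -> name reproduces the truth CE label and
    block counts for noise-free alleles at every panel locus."""
    from amplistr.panel import default_panel
    from amplistr.simulate import _random_str_allele
    panel = default_panel()
    locus = panel.str_loci[panel_index]
    seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    allele = _random_str_allele(locus, rng)
    read = build_allele_sequence(locus, allele)
    groups, unassigned = assign_reads_to_loci([(read, 1000)], panel)
    assert unassigned == 0
    reported = report_sequence_alleles(groups[locus.name], locus, panel)
    assert len(reported) == 1
    assert reported[0].counts == allele.counts
    expected_ce = ce_allele_number(locus.structure, allele.counts,
                                   locus.canonical_motif_len, 0)
    assert reported[0].ce_label == expected_ce
    assert reported[0].bracketed == bracketed_name(locus.structure, allele.counts)


def test_bracketed_name_skips_absent_blocks():
    blocks = (MotifBlock("TCTA", 0, 8), MotifBlock("TGA", 0, 1, "partial"),
              MotifBlock("TCTA", 0, 16))
    assert bracketed_name(blocks, (5, 0, 8)) == "[TCTA]5 [TCTA]8"
    assert build_inner_sequence(blocks, (2, 1, 1)) == "TCTA" * 2 + "TGA" + "TCTA"
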