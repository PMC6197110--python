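import itertools
from dataclasses import replace

import numpy as np
import pytest

from amplistr.panel import PanelConfig
from amplistr.simulate import (SimulationParams, TruthAllele, TruthProfile,
                               build_allele_sequence, draw_locus_reads,
                               generate_stutters, random_truth_profile,
                               simulate_mixture, simulate_reads,
                               simulate_sample, write_fastq)
from amplistr.strtyping import build_inner_sequence

from conftest import make_str_locus


def uniform_params(panel, depth=2000.0, **kw):
    means = {l.name: depth for l in panel.str_loci}
    means.update({l.name: depth for l in panel.snp_loci})
    return SimulationParams(depth_means=means, **kw)


class TestBuildAlleleSequence:
    def test_two_block_length(self, panel):
        d12 = panel.str_locus("D12S391")
        seq = build_allele_sequence(d12, TruthAllele((12, 9)))
        flanks = len(d12.upstream_flank) + len(d12.downstream_flank)
        assert len(seq) == flanks + 84  # 21 units x 4 bases

    def test_upstream_deletion_shortens_flank(self, panel):
        pd = panel.str_locus("PentaD")
        allele = TruthAllele(
            (5,), (("deletion", "upstream", len(pd.upstream_flank) - 13, 13),))
        seq = build_allele_sequence(pd, allele)
        expected = (len(pd.upstream_flank) - 13 + 25 + len(pd.downstream_flank))
        assert len(seq) == expected

    def test_no_variants_is_reference_exactly(self, panel):
        fga = panel.str_locus("FGA")
        allele = TruthAllele((12,))
        seq = build_allele_sequence(fga, allele)
        assert seq == (fga.upstream_flank
                       + build_inner_sequence(fga.structure, (12,))
                       + fga.downstream_flank)

    def test_variant_outside_flank_rejected(self, panel):
        fga = panel.str_locus("FGA")
        with pytest.raises(ValueError):
            build_allele_sequence(
                fga, TruthAllele((12,), (("deletion", "upstream", 15, 13),)))


class TestGenerateStutters:
    def test_d21s11_single_unit_deletions_enumerate_six_sequences(self, panel):
        """Brute-force oracle: deleting one unit from any counting block of
        the printed allele-27 structure yields exactly 6 distinct
        sequences, and the generator proposes exactly those."""
        d21 = panel.str_locus("D21S11")
        counts = (6, 5, 3, 1, 3, 1, 2, 1, 8)
        unit_blocks = [i for i, b in enumerate(d21.structure)
                       if b.ce_role == "unit" and counts[i] >= 1]
        oracle = set()
        for i in unit_blocks:
            c = list(counts)
            c[i] -= 1
            oracle.add(build_inner_sequence(d21.structure, tuple(c)))
        assert len(oracle) == 6

        params = SimulationParams(stutter_floor_repeats=0,
                                  stutter_slope_by_motif_len={4: 0.01},
                                  n2_fraction=0.0, np1_fraction=0.0)
        specs = generate_stutters(counts, d21, params)
        produced = {build_inner_sequence(d21.structure, s.counts) for s in specs}
        assert produced == oracle

    def test_compound_allele_yields_two_same_length_stutters(self, panel):
        # blocks of 6 and 8 TCTA units both exceed the default floor
        d21 = panel.str_locus("D21S11")
        counts = (6, 5, 3, 1, 3, 1, 2, 1, 8)
        specs = generate_stutters(counts, d21, SimulationParams())
        n1 = [s for s in specs if s.relation == "n-1"]
        assert len({build_inner_sequence(d21.structure, s.counts)
                    for s in n1}) >= 2

    def test_below_floor_produces_no_stutter(self):
        locus = make_str_locus(motif="AGAT", lo=0, hi=10)
        specs = generate_stutters((3,), locus, SimulationParams())
        assert specs == []

    def test_rate_linear_in_uninterrupted_length(self):
        locus = make_str_locus(motif="AGAT", lo=0, hi=20)
        params = SimulationParams()
        r10 = generate_stutters((10,), locus, params)
        r14 = generate_stutters((14,), locus, params)
        n1_10 = next(s for s in r10 if s.relation == "n-1")
        n1_14 = next(s for s in r14 if s.relation == "n-1")
        assert n1_14.rate == pytest.approx(n1_10.rate + 4 * 0.012)


class TestDrawLocusReads:
    def test_noise_free_reads_identical_to_truth(self, panel, rng):
        fga = panel.str_locus("FGA")
        params = SimulationParams().noise_free()
        a1, a2 = TruthAllele((12,)), TruthAllele((13,))
        sim = draw_locus_reads([(a1, 500.0), (a2, 500.0)], fga, params, rng)
        truth_seqs = {build_allele_sequence(fga, a1),
                      build_allele_sequence(fga, a2)}
        assert {s for s, _n, _e in sim.reads} == truth_seqs
        assert sim.stutter_reads == 0 and sim.error_reads == 0

    def test_conservation_of_read_counts(self, panel, rng):
        fga = panel.str_locus("FGA")
        sim = draw_locus_reads([(TruthAllele((12,)), 500.0),
                                (TruthAllele((13,)), 500.0)],
                               fga, SimulationParams(), rng)
        # every emitted read is a clean parent read, a stutter or an error
        assert sim.total_reads == (sum(sim.allele_reads.values())
                                   + sim.stutter_reads + sim.error_reads)

    def test_configured_stutter_ratio_recovered(self, rng):
        # rate 0.10 at deep coverage: binomial 3-sigma band
        locus = make_str_locus(motif="AGAT", lo=0, hi=20,
                               stutter_threshold_n1=0.5)
        params = SimulationParams(
            depth_means={locus.name: 20000.0}, base_error_rate=0.0,
            hb_log_sd=0.0, depth_log_sd=0.0, n2_fraction=0.0, np1_fraction=0.0,
            stutter_slope_by_motif_len={4: 0.02}, stutter_floor_repeats=7)
        # allele of 12 units: rate = 0.02 * (12 - 7) = 0.10
        sim = draw_locus_reads([(TruthAllele((12,)), 1000.0)], locus, params, rng)
        parent = sum(sim.allele_reads.values())
        ratio = sim.stutter_reads / parent
        assert 0.09 <= ratio <= 0.11

    def test_template_poisson_dropout_at_lowest_input(self, panel):
        """At 7.8 pg nearly every replicate of a heterozygous panel loses
        at least one allele (about 9% zero-template chance per allele
        across roughly 60 heterozygous alleles)."""
        rng = np.random.default_rng(77)
        params = uniform_params(panel)
        truth = random_truth_profile(panel, rng, "d", sex="F", het_rate=1.0)
        reps_with_dropout = 0
        n_reps = 25
        for _ in range(n_reps):
            dropped = False
            for locus in panel.str_loci:
                alleles = truth.str_alleles.get(locus.name)
                if not alleles:
                    continue
                sim = draw_locus_reads(
                    [(a, 7.8 / 2) for a in alleles], locus,
                    replace(params, input_pg=7.8), rng, total_input_pg=7.8)
                if len(sim.allele_reads) < len(set(alleles)):
                    dropped = True
                    break
            reps_with_dropout += dropped
        assert reps_with_dropout / n_reps > 0.9


class TestSampleSimulation:
    def test_same_seed_byte_identical_fastq(self, toy_panel, tmp_path):
        truth = TruthProfile(
            "s", "F", {"TOY1": (TruthAllele((8,)), TruthAllele((10,)))},
            {"rsTOY": ("A", "G")})
        params = SimulationParams(depth_means={"TOY1": 800.0, "rsTOY": 400.0})
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_sample(truth, toy_panel, params, p1, seed=99)
        simulate_sample(truth, toy_panel, params, p2, seed=99)
        assert p1.read_bytes() == p2.read_bytes()

    def test_manifest_totals_match_fastq_record_count(self, toy_panel, tmp_path):
        truth = TruthProfile(
            "s", "F", {"TOY1": (TruthAllele((8,)), TruthAllele((10,)))},
            {"rsTOY": ("A", "A")})
        params = SimulationParams(depth_means={"TOY1": 800.0, "rsTOY": 400.0})
        fq = tmp_path / "s.fastq"
        sim = simulate_sample(truth, toy_panel, params, fq,
                              tmp_path / "m.tsv", seed=3)
        n_records = sum(1 for line in fq.open() if line.startswith("@s:"))
        assert n_records == sim.total_reads

    def test_gzip_output_supported(self, toy_panel, tmp_path):
        truth = TruthProfile("s", "F", {"TOY1": (TruthAllele((8,)),) * 2},
                             {"rsTOY": ("A", "G")})
        params = SimulationParams(depth_means={"TOY1": 100.0, "rsTOY": 100.0})
        rng = np.random.default_rng(5)
        sim = simulate_reads([(truth, 1000.0)], toy_panel, params, rng)
        out = tmp_path / "s.fastq.gz"
        write_fastq(sim, out)
        import gzip
        with gzip.open(out, "rt") as fh:
            assert fh.readline().startswith("@")

    def test_mixture_pools_templates_of_shared_alleles(self, toy_panel):
        rng = np.random.default_rng(8)
        shared = TruthAllele((8,))
        a = TruthProfile("a", "F", {"TOY1": (shared, TruthAllele((10,)))},
                         {"rsTOY": ("A", "A")})
        b = TruthProfile("b", "F", {"TOY1": (shared, TruthAllele((12,)))},
                         {"rsTOY": ("G", "G")})
        params = SimulationParams(depth_means={"TOY1": 5000.0, "rsTOY": 1000.0},
                                  hb_log_sd=0.0, depth_log_sd=0.0,
                                  base_error_rate=0.0)
        sim = simulate_mixture(a, b, 1.0, toy_panel, params, rng=rng)
        reads = sim.loci["TOY1"].allele_reads
        names = {k: v for k, v in reads.items()}
        shared_reads = sum(v for k, v in names.items() if "]8" in k)
        other = [v for k, v in names.items() if "]8" not in k]
        # the shared allele received both contributors' templates
        assert shared_reads > 1.3 * max(other)

    def test_zero_minor_weight_equals_single_source(self, toy_panel):
        rng = np.random.default_rng(9)
        a = TruthProfile("a", "F", {"TOY1": (TruthAllele((8,)),) * 2},
                         {"rsTOY": ("A", "A")})
        b = TruthProfile("b", "F", {"TOY1": (TruthAllele((12,)),) * 2},
                         {"rsTOY": ("G", "G")})
        params = SimulationParams(depth_means={"TOY1": 2000.0, "rsTOY": 500.0})
        sim = simulate_mixture(a, b, 1e9, toy_panel, params, rng=rng)
        assert all("]12" not in k for k in sim.loci["TOY1"].allele_reads)


class TestTruthProfiles:
    def test_female_profiles_have_no_y_alleles(self, panel, rng):
        truth = random_truth_profile(panel, rng, "f", sex="F")
        truth.validate(panel)
        y_names = {l.name for l in panel.str_loci if l.ploidy_class == "Y"}
        assert not (set(truth.str_alleles) & y_names)

    def test_male_profiles_cover_dual_amplicon_loci(self, panel, rng):
        truth = random_truth_profile(panel, rng, "m", sex="M")
        truth.validate(panel)
        assert len(truth.str_alleles["DYS385a/b"]) == 2
        assert len(truth.str_alleles["DYS389I"]) == 1

    def test_counts_within_block_bounds(self, panel, rng):
        truth = random_truth_profile(panel, rng, "x", sex="M")
        for name, alleles in truth.str_alleles.items():
            locus = panel.str_locus(name)
            for allele in alleles:
                for block, count in zip(locus.structure, allele.counts):
                    assert block.min_count <= count <= block.max_count
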